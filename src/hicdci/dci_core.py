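"""Distance-decay normalization and the differential chromatin interaction score.

The differential chromatin interaction (DCI) statistic asks, for every
fixed-width genomic bin, whether that bin's interactions with its
flanking bins (within a genomic distance bound ``D``, default 200 kb)
differ between two conditions. The pipeline per chromosome is:

1. normalize each replicate's raw contact matrix by the mean count over
   all bin pairs at the same genomic distance (zero pairs included), so
   every distance stratum has mean 1 — this removes the dominant
   distance decay of Hi-C signal and makes replicates of different
   sequencing depth directly comparable;
2. for every bin, collect its *contact score array*: the normalized
   values at signed flank distances −D_bins…−1, +1…+D_bins (the
   self-interaction diagonal is excluded; arrays truncate at
   chromosome ends);
3. run a paired t-test on every (control replicate, treatment
   replicate) pair of arrays, combine the m×n two-sided p-values with
   Fisher's method (χ² with 2·m·n df), and report the signed score
   S = sign(Σt) · (−log10 p_combined).

Positive S means increased interactions in treatment relative to
control. P-values are floored at 1e-300 so scores stay finite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .contact_io import ContactMatrix, SampleSet, validate_sample_sets
from .errors import ConfigurationError, ValidationError
from .genome import GenomeBins

logger = logging.getLogger(__name__)

__all__ = [
    "P_FLOOR",
    "NormalizedMatrix",
    "ContactScoreArray",
    "DCIProfile",
    "normalize_by_distance",
    "extract_contact_score_array",
    "paired_t",
    "fisher_combine",
    "dci_score",
    "compute_dci_profile",
    "coverage_vectors",
    "adjust_for_coverage",
    "bound_vs_unbound_test",
]

P_FLOOR = 1e-300
"""Lower clamp applied to every p-value before logs and Fisher combination."""


@dataclass
class NormalizedMatrix:
    """Distance-normalized contact band for one chromosome.

    ``band[d, i]`` holds the normalized score n_{i, i+d} for genomic
    distance d (in bins), d = 0 … D_bins; entries with i + d beyond the
    chromosome are zero padding. Each distance stratum with nonzero raw
    mean averages exactly 1.
    """

    chrom: str
    band: np.ndarray  # (D_bins + 1, N)
    D_bins: int

    @property
    def n_bins(self) -> int:
        return self.band.shape[1]

    def value(self, i: int, j: int) -> float:
        d = abs(i - j)
        return float(self.band[d, min(i, j)])


@dataclass
class ContactScoreArray:
    """Normalized scores between one bin and its flanking bins.

    ``positions`` are the signed flank distances actually present
    (ascending, δ = 0 excluded, truncated at chromosome ends);
    ``values[k]`` is the normalized contact between the bin and the bin
    at offset ``positions[k]``.
    """

    bin: int
    positions: np.ndarray
    values: np.ndarray


def normalize_by_distance(m: ContactMatrix, D_bins: int) -> NormalizedMatrix:
    """Divide each count by the mean count at its genomic distance.

    The mean at distance d runs over all N − d intra-chromosomal pairs
    at that distance, zero-count pairs included; strata whose mean is
    zero normalize to zero. The result is invariant to scaling the
    whole matrix (sequencing depth).
    """
    n = m.n_bins
    if D_bins < 1:
        raise ConfigurationError(f"D_bins must be >= 1, got {D_bins}")
    if D_bins > n - 1:
        raise ConfigurationError(
            f"{m.chrom}: distance bound {D_bins} bins exceeds chromosome "
            f"extent ({n} bins)"
        )
    band = np.zeros((D_bins + 1, n))
    for d in range(D_bins + 1):
        diag = np.asarray(m.counts.diagonal(d)).ravel()
        mean_d = diag.sum() / (n - d)
        if mean_d > 0:
            band[d, : n - d] = diag / mean_d
    return NormalizedMatrix(m.chrom, band, D_bins)


def _flank_matrix(nm: NormalizedMatrix) -> np.ndarray:
    """All contact score arrays of a chromosome as one (N, 2·D_bins) table.

    Column k < D_bins is flank distance δ = k − D_bins (upstream);
    column D_bins + k is δ = k + 1 (downstream). Positions outside the
    chromosome are NaN.
    """
    D, n = nm.D_bins, nm.n_bins
    v = np.full((n, 2 * D), np.nan)
    for k in range(1, D + 1):
        v[k:, D - k] = nm.band[k, : n - k]  # δ = −k
        v[: n - k, D + k - 1] = nm.band[k, : n - k]  # δ = +k
    return v


def extract_contact_score_array(
    nm: NormalizedMatrix, bin: int, D_bins: int | None = None
) -> ContactScoreArray:
    """Contact score array of one bin (local index on nm's chromosome)."""
    D = nm.D_bins if D_bins is None else D_bins
    if D > nm.D_bins:
        raise ConfigurationError(f"requested D_bins {D} exceeds normalized band {nm.D_bins}")
    n = nm.n_bins
    deltas = np.concatenate([np.arange(-D, 0), np.arange(1, D + 1)])
    valid = (bin + deltas >= 0) & (bin + deltas < n)
    deltas = deltas[valid]
    values = np.array([nm.value(bin, bin + int(d)) for d in deltas])
    return ContactScoreArray(bin, deltas, values)


def _paired_t_rows(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise paired t on difference vectors with NaN-masked entries.

    Returns (t, p, L). Zero-variance rows: all-zero differences give
    (0, 1); a nonzero constant difference gives (±inf, P_FLOOR).
    Rows with L < 2 get NaN t and p (callers decide how to treat them).
    """
    diffs = np.atleast_2d(diffs)
    L = np.sum(~np.isnan(diffs), axis=1)
    t = np.full(diffs.shape[0], np.nan)
    p = np.full(diffs.shape[0], np.nan)
    ok = L >= 2
    if not ok.any():
        return t, p, L
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(ok[:, None], diffs, np.nan), axis=1)
        sd = np.nanstd(np.where(ok[:, None], diffs, np.nan), axis=1, ddof=1)
    zero_sd = ok & (sd == 0)
    t[zero_sd & (mean == 0)] = 0.0
    p[zero_sd & (mean == 0)] = 1.0
    shifted = zero_sd & (mean != 0)
    t[shifted] = np.sign(mean[shifted]) * np.inf
    p[shifted] = P_FLOOR
    reg = ok & (sd > 0)
    if reg.any():
        t[reg] = mean[reg] / (sd[reg] / np.sqrt(L[reg]))
        p[reg] = np.maximum(
            2.0 * stats.t.sf(np.abs(t[reg]), L[reg] - 1), P_FLOOR
        )
    return t, p, L


def paired_t(a: ContactScoreArray, b: ContactScoreArray) -> tuple[float, float]:
    """Two-sided paired t-test on differences b − a (treatment − control).

    The two arrays must cover identical flank positions (chromosome
    geometry guarantees this across replicates and conditions).
    """
    if not np.array_equal(a.positions, b.positions):
        raise ValidationError("contact score arrays cover different flank positions")
    if len(a.values) < 2:
        raise ValidationError(
            f"paired t-test undefined on arrays of length {len(a.values)}"
        )
    t, p, _ = _paired_t_rows((b.values - a.values)[None, :])
    return float(t[0]), float(p[0])


def fisher_combine(ps: list[float] | np.ndarray) -> float:
    """Fisher's combined probability: χ² = −2 Σ ln pᵢ on 2k df."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise ValidationError("fisher_combine requires at least one p-value")
    if (ps > 1).any() or (ps < 0).any():
        raise ValidationError("p-values must lie in [0, 1]")
    ps = np.maximum(ps, P_FLOOR)
    # sort before summing so the result is invariant to pair enumeration order
    chi2 = -2.0 * np.sum(np.log(np.sort(ps)))
    return float(max(stats.chi2.sf(chi2, 2 * ps.size), P_FLOOR))


def _sign_of_t_sum(ts: np.ndarray) -> int:
    """Sign of the sum of t statistics; opposing infinities cancel to 0."""
    pos_inf = np.isposinf(ts).sum()
    neg_inf = np.isneginf(ts).sum()
    if pos_inf or neg_inf:
        if pos_inf > neg_inf:
            return 1
        if neg_inf > pos_inf:
            return -1
        ts = ts[np.isfinite(ts)]
    s = math.fsum(ts)  # exact, so condition swap negates the sign exactly
    return int(np.sign(s)) if s != 0 else 0


def dci_score(
    controls: list[ContactScoreArray], treatments: list[ContactScoreArray]
) -> tuple[float, float, int]:
    """Signed DCI score for one bin from replicate contact score arrays.

    Every (control, treatment) replicate pair is tested (m×n paired
    t-tests); the p-values are Fisher-combined, and the sign is that of
    the summed t statistics (majority rule with magnitude tie-break).
    Returns (S, p, sign) with S = sign · (−log10 p).
    """
    if not controls or not treatments:
        raise ValidationError("need at least one array per condition")
    ts, ps = [], []
    for c in controls:
        for t in treatments:
            tt, pp = paired_t(c, t)
            ts.append(tt)
            ps.append(pp)
    p = fisher_combine(ps)
    sign = _sign_of_t_sum(np.array(ts))
    return sign * -np.log10(p), p, sign


@dataclass
class DCIProfile:
    """Genome-wide per-bin differential chromatin interaction profile.

    ``scores[i] = signs[i] * (-log10 p_values[i])`` for scored bins;
    bins with no contacts in any replicate of either condition are
    flagged ``no_data`` and carry S = 0, p = 1. ``n_tests`` is the
    number of Fisher-combined t-tests per bin (m·n replicate pairs).
    """

    bins: GenomeBins
    scores: np.ndarray
    p_values: np.ndarray
    signs: np.ndarray
    no_data: np.ndarray
    n_tests: int
    D: int

    def to_frame(self) -> pd.DataFrame:
        df = self.bins.to_frame()
        df["S"] = self.scores
        df["p"] = self.p_values
        df["sign"] = self.signs
        df["n_tests"] = self.n_tests
        df["no_data"] = self.no_data.astype(int)
        return df

    def write_bedgraph(self, path) -> None:
        df = self.to_frame()[["chrom", "start", "end", "S"]]
        df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")

    def write_table(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def compute_dci_profile(
    treatment: SampleSet, control: SampleSet, D: int = 200_000
) -> DCIProfile:
    """Scan all chromosomes and score every non-overlapping bin.

    ``D`` is the genomic distance bound in base pairs (default 200 kb)
    and must be a positive multiple of the bin size.
    """
    bins = validate_sample_sets(treatment, control)
    if D <= 0 or D % bins.bin_size != 0:
        raise ConfigurationError(
            f"genomic distance {D} must be a positive multiple of bin size "
            f"{bins.bin_size}"
        )
    D_bins = D // bins.bin_size
    n_total = bins.n_bins
    m, n = control.n_replicates, treatment.n_replicates
    scores = np.zeros(n_total)
    p_values = np.ones(n_total)
    signs = np.zeros(n_total, dtype=np.int8)
    no_data = np.zeros(n_total, dtype=bool)

    for chrom in bins.chrom_names:
        off = bins.offset(chrom)
        nb = bins.n_bins_chrom(chrom)
        ctrl_v = [
            _flank_matrix(normalize_by_distance(rep[chrom], D_bins))
            for rep in control.replicates
        ]
        treat_v = [
            _flank_matrix(normalize_by_distance(rep[chrom], D_bins))
            for rep in treatment.replicates
        ]
        with np.errstate(invalid="ignore"):
            any_signal = np.zeros(nb, dtype=bool)
            for v in ctrl_v + treat_v:
                any_signal |= np.nansum(np.abs(v), axis=1) > 0

        t_sum_parts = []
        log_parts = []
        valid = np.ones(nb, dtype=bool)
        for cv in ctrl_v:
            for tv in treat_v:
                t, p, L = _paired_t_rows(tv - cv)
                row_ok = L >= 2
                valid &= row_ok
                t_sum_parts.append(t)
                log_parts.append(np.where(row_ok, np.log(np.where(row_ok, p, 1.0)), 0.0))
        k = m * n
        # per-bin sort across pairs makes the chi-square sum invariant to
        # pair enumeration order (so swapping conditions preserves p exactly)
        chi2 = -2.0 * np.sum(np.sort(np.vstack(log_parts), axis=0), axis=0)
        p_comb = np.maximum(stats.chi2.sf(chi2, 2 * k), P_FLOOR)
        t_stack = np.vstack(t_sum_parts)
        sign_row = np.array([_sign_of_t_sum(t_stack[:, i]) for i in range(nb)], dtype=np.int8)

        scored = any_signal & valid
        sl = slice(off, off + nb)
        no_data[sl] = ~scored
        p_values[sl][:] = np.where(scored, p_comb, 1.0)
        signs[sl][:] = np.where(scored, sign_row, 0)
        scores[sl][:] = np.where(scored, sign_row * -np.log10(np.where(scored, p_comb, 1.0)), 0.0)
        # slices of numpy arrays are views; the [:] assignments above mutate in place
    return DCIProfile(bins, scores, p_values, signs, no_data, m * n, D)


def coverage_vectors(sample_set: SampleSet, D: int) -> list[np.ndarray]:
    """Per-replicate raw coverage: row sums of counts within the ±D band.

    The diagonal is included — self-ligation counts track per-bin read
    coverage, the confounder the regression adjustment absorbs.
    """
    bins = sample_set.bins
    D_bins = D // bins.bin_size
    out = []
    for rep in sample_set.replicates:
        cov = np.zeros(bins.n_bins)
        for chrom in bins.chrom_names:
            off = bins.offset(chrom)
            nb = bins.n_bins_chrom(chrom)
            m = rep[chrom].counts
            row = np.zeros(nb)
            for d in range(0, min(D_bins, nb - 1) + 1):
                diag = np.asarray(m.diagonal(d)).ravel()
                row[: nb - d] += diag
                if d > 0:
                    row[d:] += diag
            cov[off : off + nb] = row
        out.append(cov)
    return out


def adjust_for_coverage(
    profile: DCIProfile,
    treatment_cov: list[np.ndarray],
    control_cov: list[np.ndarray],
) -> DCIProfile:
    """Regress out per-bin coverage change from the DCI scores.

    Covariate x_i = log2((mean treatment coverage + 1) /
    (mean control coverage + 1)); the adjusted score is the residual of
    an ordinary least-squares fit of S on x over scored bins. No-data
    bins are untouched. The returned profile's p/sign fields are kept
    from the unadjusted profile — after adjustment the score is a
    residual, not sign·(−log10 p).
    """
    x = np.log2(
        (np.mean(treatment_cov, axis=0) + 1.0) / (np.mean(control_cov, axis=0) + 1.0)
    )
    if x.shape != profile.scores.shape:
        raise ValidationError("coverage vectors not aligned with profile bins")
    mask = ~profile.no_data
    if mask.sum() < 3:
        raise ValidationError("coverage adjustment requires at least 3 scored bins")
    xs, ys = x[mask], profile.scores[mask]
    var = np.var(xs)
    if var == 0:
        logger.warning("coverage covariate is constant; returning profile unchanged")
        return replace(profile, scores=profile.scores.copy())
    slope = np.cov(xs, ys, bias=True)[0, 1] / var
    intercept = ys.mean() - slope * xs.mean()
    adjusted = profile.scores.copy()
    adjusted[mask] = ys - (intercept + slope * xs)
    return replace(profile, scores=adjusted)


def bound_vs_unbound_test(
    profile: DCIProfile, sites: pd.DataFrame
) -> tuple[float, float]:
    """Wilcoxon rank-sum of DCI scores at bins with vs without binding sites.

    ``sites`` is a BED-like frame (chrom, start, end). Scored bins are
    partitioned by whether they overlap at least one site; returns the
    rank-sum W of the bound group and the two-sided p (exact for small
    tie-free samples, tie-corrected normal approximation otherwise).
    """
    bins = profile.bins
    bound = np.zeros(bins.n_bins, dtype=bool)
    bs = bins.bin_size
    for chrom, start, end in sites[["chrom", "start", "end"]].itertuples(index=False):
        if chrom not in bins.chrom_names:
            continue
        lo = max(0, int(start) // bs)
        hi = min(bins.n_bins_chrom(chrom), -(-int(end) // bs))
        if hi > lo:
            off = bins.offset(chrom)
            bound[off + lo : off + hi] = True
    scored = ~profile.no_data
    s_bound = profile.scores[scored & bound]
    s_unbound = profile.scores[scored & ~bound]
    if len(s_bound) == 0 or len(s_unbound) == 0:
        raise ValidationError("one of the bound/unbound partitions is empty")
    res = stats.mannwhitneyu(s_bound, s_unbound, alternative="two-sided", method="auto")
    n1 = len(s_bound)
    w = float(res.statistic + n1 * (n1 + 1) / 2)  # U -> rank-sum of bound group
    return w, float(res.pvalue)
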
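"""Transcriptional regulator inference from a scored cis-regulatory profile.

Given a compendium of binary TR binding profiles over the CRE catalog
(one vector per ChIP-seq dataset, several datasets per TR), each
dataset is scored by the AUROC of its bound CREs against the
score-ranked CRE list: an AUROC above 0.5 means the dataset's binding
concentrates at CREs with high differential-interaction scores. Per-TR
statistics aggregate the dataset AUROCs three ways:

* a one-sided Wilcoxon rank-sum of the TR's AUROCs against all other
  datasets' AUROCs;
* a z-score of the TR's mean AUROC against the distribution of all
  AUROCs;
* the TR's maximum AUROC.

Each statistic is converted to a rank quantile r = rank / N_TRs
(best TR → smallest r, ties share the mean rank); the rank sum
s = r_w + r_z + r_m is referred to the Irwin–Hall distribution (the sum
of three independent uniforms) for a final p-value, and TRs are ranked
by ascending p with a deterministic name tie-break. Running the same
analysis on the flipped profile yields the "decrease" direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb, factorial, floor
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cre_mapping import CREProfile, flip
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BindingCompendium",
    "RankedCREList",
    "TRResultTable",
    "read_compendium",
    "write_compendium",
    "rank_cres",
    "auroc",
    "wilcoxon_tr_vs_rest",
    "zscore_tr",
    "irwin_hall_p",
    "rank_trs",
]


@dataclass
class BindingCompendium:
    """Binary binding of ChIP-seq datasets over the CRE catalog.

    ``datasets`` maps row order to (dataset_id, tr_name); ``binding``
    is a (n_datasets, n_cres) boolean matrix.
    """

    datasets: list[tuple[str, str]]
    binding: np.ndarray

    def __post_init__(self) -> None:
        self.binding = np.asarray(self.binding, dtype=bool)
        if self.binding.ndim != 2 or self.binding.shape[0] != len(self.datasets):
            raise ValidationError("binding matrix shape inconsistent with dataset list")
        if len({t for _, t in self.datasets}) < 2:
            raise ValidationError("a compendium needs at least 2 distinct TRs")

    @property
    def tr_index(self) -> dict[str, list[int]]:
        idx: dict[str, list[int]] = {}
        for i, (_, tr) in enumerate(self.datasets):
            idx.setdefault(tr, []).append(i)
        return idx

    @property
    def n_cres(self) -> int:
        return self.binding.shape[1]


@dataclass
class RankedCREList:
    """Scored CRE ordinals sorted by descending score, ties by ordinal."""

    ordinals: np.ndarray
    scores: np.ndarray  # aligned with ordinals


def write_compendium(comp: BindingCompendium, prefix: str | Path) -> tuple[Path, Path]:
    """Write the TSV sidecar pair ``<prefix>_datasets.tsv`` (dataset_id,
    tr_name) and ``<prefix>_binding.tsv`` (sparse dataset_id/cre_id triplets)."""
    prefix = Path(prefix)
    ds_path = prefix.parent / (prefix.name + "_datasets.tsv")
    bind_path = prefix.parent / (prefix.name + "_binding.tsv")
    pd.DataFrame(comp.datasets, columns=["dataset_id", "tr_name"]).to_csv(
        ds_path, sep="\t", index=False
    )
    rows, cols = np.nonzero(comp.binding)
    pd.DataFrame(
        {
            "dataset_id": [comp.datasets[r][0] for r in rows],
            "cre_id": cols,
        }
    ).to_csv(bind_path, sep="\t", index=False)
    return ds_path, bind_path


def read_compendium(prefix: str | Path, n_cres: int) -> BindingCompendium:
    """Read the sidecar pair written by :func:`write_compendium`."""
    prefix = Path(prefix)
    ds = pd.read_csv(prefix.parent / (prefix.name + "_datasets.tsv"), sep="\t")
    triplets = pd.read_csv(prefix.parent / (prefix.name + "_binding.tsv"), sep="\t")
    row_of = {d: i for i, d in enumerate(ds["dataset_id"])}
    binding = np.zeros((len(ds), n_cres), dtype=bool)
    for d, c in triplets.itertuples(index=False):
        if d not in row_of:
            raise ValidationError(f"binding triplets name unknown dataset {d!r}")
        if not 0 <= int(c) < n_cres:
            raise ValidationError(f"cre_id {c} outside catalog of size {n_cres}")
        binding[row_of[d], int(c)] = True
    return BindingCompendium(list(ds.itertuples(index=False, name=None)), binding)


def rank_cres(profile: CREProfile) -> RankedCREList:
    """Scored CRE ordinals by descending score; score ties broken by ordinal."""
    ordinals = np.nonzero(profile.scored_mask)[0]
    scores = profile.score[ordinals]
    order = np.lexsort((ordinals, -scores))
    return RankedCREList(ordinals[order], scores[order])


def auroc(ranked: RankedCREList, binding: np.ndarray) -> float:
    """Mann–Whitney AUROC of a dataset's bound CREs under the score ranking.

    AUC = (R₁ − n₁(n₁+1)/2) / (n₁ n₀) with midranks for score ties,
    where R₁ is the rank-sum of bound CREs under ascending score ranks.
    Undefined (ValidationError) when all or none of the scored CREs are
    bound.
    """
    b = np.asarray(binding, dtype=bool)[ranked.ordinals]
    ranks = stats.rankdata(ranked.scores)
    return _auroc_from_ranks(ranks, b)


def _auroc_from_ranks(ascending_ranks: np.ndarray, bound: np.ndarray) -> float:
    n1 = int(bound.sum())
    n0 = len(bound) - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUROC undefined: all or none of the CREs are bound")
    r1 = ascending_ranks[bound].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def wilcoxon_tr_vs_rest(
    tr_aucs: np.ndarray, other_aucs: np.ndarray
) -> tuple[float, float]:
    """One-sided rank-sum: are the TR's AUROCs larger than the rest's?

    Exact enumeration for small tie-free samples, tie-corrected
    continuity-corrected normal approximation otherwise.
    """
    tr_aucs = np.asarray(tr_aucs, float)
    other_aucs = np.asarray(other_aucs, float)
    if len(tr_aucs) == 0 or len(other_aucs) == 0:
        raise ValidationError("both AUC lists must be non-empty")
    if len(tr_aucs) + len(other_aucs) < 3:
        raise ValidationError("rank-sum test needs at least 3 values in total")
    res = stats.mannwhitneyu(tr_aucs, other_aucs, alternative="greater", method="auto")
    return float(res.statistic), float(res.pvalue)


def zscore_tr(tr_aucs: np.ndarray, all_aucs: np.ndarray) -> float:
    """Standardized mean AUROC: (mean_TR − mean_all) / sd_all (sample sd)."""
    all_aucs = np.asarray(all_aucs, float)
    if len(all_aucs) < 2:
        raise ValidationError("z-score needs at least 2 background AUCs")
    sd = float(np.std(all_aucs, ddof=1))
    if sd == 0:
        raise ValidationError("z-score undefined: background AUCs have zero variance")
    return float((np.mean(tr_aucs) - np.mean(all_aucs)) / sd)


def irwin_hall_p(s: float, k: int) -> float:
    """CDF of the sum of k i.i.d. uniform(0,1) variables at s.

    Small rank-quantile sums mean strong association, so the lower tail
    is the p-value. Standard alternating-sum closed form:
    F(s) = (1/k!) Σ_{j=0}^{⌊s⌋} (−1)ʲ C(k,j) (s−j)ᵏ.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if not 0 <= s <= k:
        raise ValidationError(f"rank sum {s} outside [0, {k}]")
    total = sum(
        (-1) ** j * comb(k, j) * (s - j) ** k for j in range(floor(s) + 1)
    )
    return float(min(max(total / factorial(k), 0.0), 1.0))


@dataclass
class TRResultTable:
    """Ranked per-TR statistics for one direction (increase/decrease)."""

    direction: str
    table: pd.DataFrame

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def rank_trs(
    profile: CREProfile, compendium: BindingCompendium, direction: str = "increase"
) -> TRResultTable:
    """Rank all TRs by association with high (or, flipped, low) scores.

    direction="decrease" analyses the flipped profile. Datasets with
    degenerate binding (all or no scored CREs bound) are skipped; a TR
    left with zero usable datasets is dropped with a warning.
    """
    if direction not in ("increase", "decrease"):
        raise ValidationError(f"unknown direction {direction!r}")
    if compendium.n_cres != len(profile.catalog):
        raise ValidationError("compendium and profile use different CRE catalogs")
    work = flip(profile) if direction == "decrease" else profile

    ranked = rank_cres(work)
    asc_ranks = stats.rankdata(ranked.scores)
    aucs: dict[int, float] = {}
    for i, (ds_id, _tr) in enumerate(compendium.datasets):
        b = compendium.binding[i][ranked.ordinals]
        try:
            aucs[i] = _auroc_from_ranks(asc_ranks, b)
        except ValidationError:
            logger.warning("dataset %s skipped: degenerate binding", ds_id)

    tr_aucs: dict[str, np.ndarray] = {}
    for tr, rows in compendium.tr_index.items():
        vals = np.array([aucs[r] for r in rows if r in aucs])
        if len(vals) == 0:
            logger.warning("TR %s dropped: no usable dataset", tr)
            continue
        tr_aucs[tr] = vals
    if len(tr_aucs) < 2:
        raise ValidationError("fewer than 2 TRs with usable datasets")

    all_aucs = np.concatenate(list(tr_aucs.values()))
    names = sorted(tr_aucs)
    w_stat, w_p, z, max_auc = [], [], [], []
    for tr in names:
        own = tr_aucs[tr]
        rest = np.concatenate([v for t, v in tr_aucs.items() if t != tr])
        ws, wp = wilcoxon_tr_vs_rest(own, rest)
        w_stat.append(ws)
        w_p.append(wp)
        z.append(zscore_tr(own, all_aucs))
        max_auc.append(float(own.max()))

    n_trs = len(names)
    r_w = stats.rankdata(w_p) / n_trs  # small p best
    r_z = stats.rankdata([-v for v in z]) / n_trs  # large z best
    r_m = stats.rankdata([-v for v in max_auc]) / n_trs  # large max AUC best
    rank_sum = r_w + r_z + r_m
    ih_p = np.array([irwin_hall_p(s, 3) for s in rank_sum])

    df = pd.DataFrame(
        {
            "tr_name": names,
            "max_auc": max_auc,
            "wilcoxon_stat": w_stat,
            "wilcoxon_p": w_p,
            "z_score": z,
            "rank_sum": rank_sum,
            "irwin_hall_p": ih_p,
        }
    )
    df = df.sort_values(["irwin_hall_p", "tr_name"], kind="mergesort").reset_index(
        drop=True
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return TRResultTable(direction, df)
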
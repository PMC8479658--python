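"""Synthetic Hi-C maps, CRE catalogs and binding compendia with known truth.

The generator emulates the pipeline's full input contract at desk
scale:

* contact maps with a power-law distance decay — counts at bin
  distance d are Poisson with mean λ₀·(d+1)^−α — optionally
  overdispersed (negative binomial), symmetric and reproducible from a
  seed;
* differential "blocks": in the treatment condition, pairs whose bins
  both fall inside a block's bin range have their expected count
  multiplied by the block's fold change, implanting a gained (or, with
  fold < 1, lost) interaction neighbourhood. Keep block width at or
  below the distance bound in bins so the implanted signal lies inside
  the tested band;
* a toy CRE catalog of short intervals placed uniformly over the
  genome;
* a binding compendium in which one designated "causal" TR binds CREs
  inside blocks with probability bound_fraction·enrichment (capped at
  1) and bound_fraction elsewhere, while decoy TRs bind uniformly at
  bound_fraction.

It does not attempt TADs, compartments or loop anchors; the block
model is the minimal structure the differential statistic can detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contact_io import ContactMatrix, SampleSet, write_cool, write_hicpro
from .cre_mapping import CRECatalog
from .errors import ValidationError
from .genome import GenomeBins
from .tr_inference import BindingCompendium

__all__ = [
    "SimulationConfig",
    "simulate_contact_maps",
    "simulate_cre_catalog",
    "simulate_compendium",
    "write_fixture_dialects",
]

_COND_STREAM = {"control": 0, "treatment": 1}
_CATALOG_STREAM = 100
_COMPENDIUM_STREAM = 200


def _default_blocks() -> list[tuple[str, tuple[int, int], float]]:
    # one 40-bin (200 kb at 5 kb) gained block per chromosome, fold 3
    return [("chr1", (180, 220), 3.0), ("chr2", (80, 120), 3.0)]


@dataclass
class SimulationConfig:
    """Ground-truth study conditions for one synthetic experiment.

    Defaults describe a small two-chromosome genome (2 × 400 bins at
    5 kb) with Poisson contact counts decaying as (d+1)^−1 from a base
    depth of 100 reads at the diagonal, two replicates per condition,
    one 200 kb gained block per chromosome at fold change 3, 2000 CREs
    of 400 bp, and 50 TRs × 2 datasets binding 5% of CREs — the causal
    TR 10× enriched inside blocks.
    """

    n_chroms: int = 2
    bins_per_chrom: int = 400
    bin_size: int = 5000
    decay_exponent: float = 1.0
    base_depth: float = 100.0
    n_replicates: int = 2
    blocks: list[tuple[str, tuple[int, int], float]] = field(
        default_factory=_default_blocks
    )
    n_cres: int = 2000
    cre_width: int = 400
    n_trs: int = 50
    n_datasets_per_tr: int = 2
    bound_fraction: float = 0.05
    enrichment: float = 10.0
    dispersion: float | None = None  # negative-binomial size; None = Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.bins_per_chrom, self.bin_size) < 1:
            raise ValidationError("genome dimensions must be >= 1")
        if any(f <= 0 for _, _, f in self.blocks):
            raise ValidationError("block fold changes must be positive")
        if self.enrichment < 1:
            raise ValidationError("enrichment must be >= 1")
        if not 0 < self.bound_fraction < 1:
            raise ValidationError("bound_fraction must lie in (0, 1)")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chroms))

    def genome_bins(self) -> GenomeBins:
        length = self.bins_per_chrom * self.bin_size
        return GenomeBins(self.chrom_names, (length,) * self.n_chroms, self.bin_size)


def _expected_matrix(cfg: SimulationConfig, chrom: str, condition: str) -> np.ndarray:
    n = cfg.bins_per_chrom
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    lam = cfg.base_depth * (d + 1.0) ** (-cfg.decay_exponent)
    if condition == "treatment":
        for bchrom, (lo, hi), fold in cfg.blocks:
            if bchrom == chrom:
                inside = np.zeros(n, dtype=bool)
                inside[lo:hi] = True
                lam[np.ix_(inside, inside)] *= fold
    return lam


def _sample_counts(lam: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    iu = np.triu_indices(lam.shape[0])
    mean = lam[iu]
    if cfg.dispersion is None:
        vals = rng.poisson(mean)
    else:
        size = cfg.dispersion
        vals = rng.negative_binomial(size, size / (size + mean))
    counts = np.zeros_like(lam)
    counts[iu] = vals
    counts = counts + counts.T - np.diag(np.diag(counts))
    return counts


def simulate_contact_maps(cfg: SimulationConfig, condition: str) -> SampleSet:
    """Draw all replicates of one condition; deterministic given the seed.

    The treatment and control streams are independent substreams of
    ``cfg.seed``, so the two conditions are exchangeable draws from the
    same model when no blocks are implanted (or every fold change is 1).
    """
    if condition not in _COND_STREAM:
        raise ValidationError(f"condition must be treatment/control, got {condition!r}")
    bins = cfg.genome_bins()
    replicates = []
    for rep in range(cfg.n_replicates):
        matrices = {}
        for ci, chrom in enumerate(cfg.chrom_names):
            rng = np.random.default_rng(
                [cfg.seed, _COND_STREAM[condition], rep, ci]
            )
            lam = _expected_matrix(cfg, chrom, condition)
            counts = _sample_counts(lam, cfg, rng)
            matrices[chrom] = ContactMatrix(chrom, bins, sp.csr_matrix(counts))
        replicates.append(matrices)
    return SampleSet(condition, replicates, bins)


def simulate_cre_catalog(cfg: SimulationConfig) -> CRECatalog:
    """Place n_cres fixed-width intervals uniformly over the genome."""
    rng = np.random.default_rng([cfg.seed, _CATALOG_STREAM])
    bins = cfg.genome_bins()
    length = cfg.bins_per_chrom * cfg.bin_size
    chroms = rng.integers(0, cfg.n_chroms, cfg.n_cres)
    mids = rng.integers(cfg.cre_width, length - cfg.cre_width, cfg.n_cres)
    df = pd.DataFrame(
        {
            "chrom": [bins.chrom_names[c] for c in chroms],
            "start": mids - cfg.cre_width // 2,
            "end": mids + cfg.cre_width // 2,
        }
    ).sort_values(["chrom", "start"], kind="mergesort")
    return CRECatalog(df.reset_index(drop=True), genome="synthetic")


def _cres_in_blocks(cfg: SimulationConfig, catalog: CRECatalog) -> np.ndarray:
    bins = cfg.genome_bins()
    inside = np.zeros(len(catalog), dtype=bool)
    mids = (catalog.regions["start"] + catalog.regions["end"]).to_numpy() // 2
    local = mids // cfg.bin_size
    for i, chrom in enumerate(catalog.regions["chrom"]):
        for bchrom, (lo, hi), _fold in cfg.blocks:
            if chrom == bchrom and lo <= local[i] < hi:
                inside[i] = True
    return inside


def simulate_compendium(cfg: SimulationConfig, catalog: CRECatalog) -> BindingCompendium:
    """Draw the binding compendium; TR index 0 is the causal regulator."""
    rng = np.random.default_rng([cfg.seed, _COMPENDIUM_STREAM])
    inside = _cres_in_blocks(cfg, catalog)
    p_causal = np.where(
        inside, min(1.0, cfg.bound_fraction * cfg.enrichment), cfg.bound_fraction
    )
    datasets: list[tuple[str, str]] = []
    rows = []
    for t in range(cfg.n_trs):
        tr = "TR_causal" if t == 0 else f"TR{t:03d}"
        p = p_causal if t == 0 else np.full(len(catalog), cfg.bound_fraction)
        for d in range(cfg.n_datasets_per_tr):
            datasets.append((f"{tr}_ds{d}", tr))
            rows.append(rng.random(len(catalog)) < p)
    return BindingCompendium(datasets, np.vstack(rows))


def write_fixture_dialects(sample_set: SampleSet, outdir: str | Path) -> dict[str, list[Path]]:
    """Write every replicate in the HiC-Pro and cooler dialects.

    Returns {"hicpro": [matrix paths], "hicpro_bed": [bed paths],
    "cool": [store paths]} with one entry per replicate, enabling
    cross-dialect reader-equivalence tests. (No Juicer .hic writer is
    available as plain Python; that dialect is read-only.)
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, list[Path]] = {"hicpro": [], "hicpro_bed": [], "cool": []}
    for i, rep in enumerate(sample_set.replicates):
        prefix = outdir / f"{sample_set.condition}_rep{i}"
        mat, bed = write_hicpro(rep, prefix)
        cool = write_cool(rep, outdir / f"{sample_set.condition}_rep{i}.cool")
        paths["hicpro"].append(mat)
        paths["hicpro_bed"].append(bed)
        paths["cool"].append(cool)
    return paths
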
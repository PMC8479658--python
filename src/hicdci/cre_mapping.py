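"""Projection of the binned DCI profile onto a cis-regulatory element catalog.

Transcriptional-regulator binding happens at the scale of individual
cis-regulatory elements (CREs, ~0.1–1 kb), far below Hi-C bin size. To
bridge the two, every CRE in a fixed genome-wide catalog (the union-DHS
role) inherits the DCI score of the bin containing its midpoint,
producing a *cis-regulatory profile*. Flipping the profile (negating
every score) turns an "increased interactions" analysis into a
"decreased interactions" one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dci_core import DCIProfile
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["CRECatalog", "CREProfile", "read_bed_catalog", "map_profile_to_cres", "flip"]


@dataclass
class CRECatalog:
    """Ordered CRE intervals with dense stable ordinal IDs (row order)."""

    regions: pd.DataFrame  # columns chrom, start, end; index = ordinal 0..N-1
    genome: str = "synthetic"

    def __post_init__(self) -> None:
        r = self.regions
        if len(r) and (r["start"] >= r["end"]).any():
            raise ValidationError("CRE catalog contains empty or inverted intervals")
        self.regions = r.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class CREProfile:
    """Per-CRE DCI scores; unscored CREs are masked, never zero-filled.

    Zero is a meaningful "no change" score, so CREs falling on no-data
    bins or unknown chromosomes are excluded from ranking via
    ``scored_mask`` rather than set to 0.
    """

    catalog: CRECatalog
    score: np.ndarray  # NaN where unscored
    scored_mask: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = self.catalog.regions.copy()
        df.insert(0, "cre_id", np.arange(len(df)))
        df["score"] = self.score
        return df[self.scored_mask].reset_index(drop=True)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bed_catalog(path: str | Path, genome: str = "user") -> CRECatalog:
    """Load a BED3+ file (0-based half-open) as a CRE catalog."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return CRECatalog(df, genome=genome)


def map_profile_to_cres(profile: DCIProfile, catalog: CRECatalog) -> CREProfile:
    """Assign each CRE the DCI score of the bin containing its midpoint.

    Midpoint assignment is unambiguous for boundary-spanning CREs and
    order-independent. CREs on chromosomes absent from the profile or
    whose bin carries no data are left unscored.
    """
    if len(catalog) == 0:
        raise ValidationError("empty CRE catalog")
    bins = profile.bins
    n = len(catalog)
    score = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    chrom_index = {c: i for i, c in enumerate(bins.chrom_names)}
    for idx, (chrom, start, end) in enumerate(
        catalog.regions[["chrom", "start", "end"]].itertuples(index=False)
    ):
        if chrom not in chrom_index:
            continue
        mid = (int(start) + int(end)) // 2
        local = mid // bins.bin_size
        if local >= bins.n_bins_chrom(chrom):
            continue
        g = bins.offset(chrom) + local
        if profile.no_data[g]:
            continue
        score[idx] = profile.scores[g]
        mask[idx] = True
    if not mask.any():
        raise ValidationError("no CRE could be scored against the profile")
    n_unscored = int((~mask).sum())
    if n_unscored:
        logger.info("%d of %d CREs left unscored", n_unscored, n)
    return CREProfile(catalog, score, mask)


def flip(profile: CREProfile) -> CREProfile:
    """Negate every score; the scored mask is unchanged (an involution)."""
    return replace(profile, score=-profile.score)
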
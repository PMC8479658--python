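"""Readers and writers for intra-chromosomal Hi-C contact maps.

Three on-disk dialects of unnormalized contact maps are supported:

* the HiC-Pro pair ``<prefix>.matrix`` (tab-separated ``binID1 binID2
  count`` triplets, 1-based bin IDs) + ``<prefix>_abs.bed`` (``chrom
  start end binID``);
* single-resolution ``.cool`` stores (the cooler HDF5 layout with
  ``chroms/``, ``bins/`` and ``pixels/`` tables), accessed directly
  through h5py;
* Juicer ``.hic`` binary files, through the optional ``hicstraw``
  package.

All readers return the same in-memory representation: a
:class:`SampleSet` holding one sparse symmetric
:class:`ContactMatrix` per chromosome per replicate. Inter-chromosomal
pixels are dropped (with a logged count): the downstream statistic only
examines interactions within a bounded genomic distance on the same
chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, FormatError, ValidationError
from .genome import GenomeBins

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "SampleSet",
    "read_hicpro",
    "write_hicpro",
    "read_cool",
    "write_cool",
    "read_juicer_hic",
    "validate_sample_sets",
]


@dataclass
class ContactMatrix:
    """Symmetric raw contact counts for one chromosome of one replicate.

    ``counts`` is an N x N scipy CSR matrix (N = number of bins on the
    chromosome); absent entries mean zero observed contacts. Counts are
    raw (unnormalized) and may be floats but never negative.
    """

    chrom: str
    bins: GenomeBins
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        n = self.bins.n_bins_chrom(self.chrom)
        if self.counts.shape != (n, n):
            raise ValidationError(
                f"{self.chrom}: matrix shape {self.counts.shape} != bin count {n}"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError(f"{self.chrom}: negative contact counts")
        if (self.counts != self.counts.T).nnz != 0:
            raise ValidationError(f"{self.chrom}: contact matrix not symmetric")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass
class SampleSet:
    """All replicates of one condition ("treatment" or "control")."""

    condition: str
    replicates: list[dict[str, ContactMatrix]]
    bins: GenomeBins = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValidationError(f"{self.condition}: zero replicates")
        if self.bins is None:
            first = next(iter(self.replicates[0].values()))
            self.bins = first.bins
        for i, rep in enumerate(self.replicates):
            for cm in rep.values():
                if not cm.bins.same_grid(self.bins):
                    raise ValidationError(
                        f"{self.condition} replicate {i}: inconsistent binning"
                    )

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def _symmetrize(m: sp.coo_matrix) -> sp.csr_matrix:
    """Mirror one-sided triplets: keep (i,j) and (j,i), diagonal once."""
    m = m.tocsr()
    return (m + m.T - sp.diags(m.diagonal())).tocsr()


def _bins_from_bed(bed: pd.DataFrame) -> tuple[GenomeBins, dict[int, tuple[str, int]]]:
    """Build GenomeBins from a HiC-Pro abs.bed table; validate widths."""
    widths = bed["end"] - bed["start"]
    bin_size = int(widths.mode().iloc[0])
    chroms, lengths = [], []
    id_map: dict[int, tuple[str, int]] = {}
    for chrom, grp in bed.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        w = (grp["end"] - grp["start"]).to_numpy()
        if (w[:-1] != bin_size).any() or w[-1] > bin_size:
            raise FormatError(
                f"{chrom}: non-uniform bin width (only the terminal bin may be short)"
            )
        starts = grp["start"].to_numpy()
        if (starts != np.arange(len(grp)) * bin_size).any():
            raise FormatError(f"{chrom}: bins do not tile the chromosome contiguously")
        chroms.append(str(chrom))
        lengths.append(int(grp["end"].max()))
        for local, bid in enumerate(grp["binID"]):
            id_map[int(bid)] = (str(chrom), local)
    bins = GenomeBins(tuple(chroms), tuple(lengths), bin_size)
    return bins, id_map


def read_hicpro(matrix_path: str | Path, bed_path: str | Path) -> dict[str, ContactMatrix]:
    """Read one HiC-Pro raw matrix (+ abs.bed) into per-chromosome matrices.

    Only intra-chromosomal triplets are retained; the number of dropped
    inter-chromosomal pixels is logged. Counts are symmetrized so both
    (i, j) and (j, i) are stored.
    """
    bed = pd.read_csv(
        bed_path, sep=r"\s+", header=None, names=["chrom", "start", "end", "binID"]
    )
    bins, id_map = _bins_from_bed(bed)
    try:
        trip = pd.read_csv(
            matrix_path, sep=r"\s+", header=None, names=["i", "j", "count"]
        )
    except pd.errors.EmptyDataError:
        trip = pd.DataFrame(columns=["i", "j", "count"])
    if len(trip) and (trip["count"] < 0).any():
        raise ValidationError(f"{matrix_path}: negative counts")
    unknown = set(trip["i"]).union(trip["j"]) - set(id_map)
    if unknown:
        raise FormatError(
            f"{matrix_path}: bin IDs {sorted(unknown)[:5]} absent from {bed_path}"
        )

    per_chrom: dict[str, list[tuple[int, int, float]]] = {c: [] for c in bins.chrom_names}
    n_inter = 0
    for i, j, c in trip.itertuples(index=False):
        chrom_i, li = id_map[int(i)]
        chrom_j, lj = id_map[int(j)]
        if chrom_i != chrom_j:
            n_inter += 1
            continue
        per_chrom[chrom_i].append((li, lj, float(c)))
    if n_inter:
        logger.info("%s: dropped %d inter-chromosomal pixels", matrix_path, n_inter)

    out = {}
    for chrom in bins.chrom_names:
        n = bins.n_bins_chrom(chrom)
        t = per_chrom[chrom]
        if t:
            ii, jj, cc = zip(*t)
            m = sp.coo_matrix((cc, (ii, jj)), shape=(n, n))
        else:
            m = sp.coo_matrix((n, n))
        out[chrom] = ContactMatrix(chrom, bins, _symmetrize(m))
    return out


def write_hicpro(
    matrices: dict[str, ContactMatrix], prefix: str | Path
) -> tuple[Path, Path]:
    """Write matrices as ``<prefix>.matrix`` + ``<prefix>_abs.bed``.

    Upper-triangle triplets with 1-based sequential bin IDs, matching
    the dialect :func:`read_hicpro` accepts.
    """
    prefix = Path(prefix)
    bins = next(iter(matrices.values())).bins
    bed = bins.to_frame()
    bed["binID"] = np.arange(1, len(bed) + 1)
    bed_path = prefix.parent / (prefix.name + "_abs.bed")
    mat_path = prefix.parent / (prefix.name + ".matrix")
    bed.to_csv(bed_path, sep="\t", header=False, index=False)

    rows = []
    for chrom in bins.chrom_names:
        off = bins.offset(chrom) + 1  # 1-based IDs
        upper = sp.triu(matrices[chrom].counts).tocoo()
        for i, j, c in zip(upper.row, upper.col, upper.data):
            rows.append((off + i, off + j, c))
    with open(mat_path, "w") as fh:
        for i, j, c in sorted(rows):
            cs = f"{int(c)}" if float(c).is_integer() else f"{c}"
            fh.write(f"{i}\t{j}\t{cs}\n")
    return mat_path, bed_path


def _decode(arr) -> list[str]:
    return [x.decode() if isinstance(x, bytes) else str(x) for x in arr]


def read_cool(path: str | Path, bin_size: int | None = None) -> dict[str, ContactMatrix]:
    """Read raw counts from a single-resolution cooler store.

    ``bin_size``, when given, must match the store's resolution; a
    multi-resolution file requires it to select the resolution group.
    """
    with h5py.File(path, "r") as f:
        if "resolutions" in f:
            if bin_size is None:
                avail = sorted(int(k) for k in f["resolutions"])
                raise ConfigurationError(
                    f"{path}: multi-resolution store; choose bin_size from {avail}"
                )
            key = f"resolutions/{bin_size}"
            if key not in f:
                avail = sorted(int(k) for k in f["resolutions"])
                raise ConfigurationError(
                    f"{path}: resolution {bin_size} unavailable; has {avail}"
                )
            grp = f[key]
        else:
            grp = f
        store_bs = int(grp.attrs.get("bin-size", 0)) or int(
            np.max(grp["bins/end"][:] - grp["bins/start"][:])
        )
        if bin_size is not None and store_bs != bin_size:
            raise ConfigurationError(
                f"{path}: store bin size {store_bs} != requested {bin_size}"
            )
        chrom_names = _decode(grp["chroms/name"][:])
        chrom_lengths = tuple(int(x) for x in grp["chroms/length"][:])
        bins = GenomeBins(tuple(chrom_names), chrom_lengths, store_bs)

        bchrom = grp["bins/chrom"][:]
        if bchrom.dtype.kind in "SOU":
            bin_chrom_idx = np.array(
                [chrom_names.index(c) for c in _decode(bchrom)], dtype=np.int64
            )
        else:
            bin_chrom_idx = bchrom.astype(np.int64)
        b1 = grp["pixels/bin1_id"][:].astype(np.int64)
        b2 = grp["pixels/bin2_id"][:].astype(np.int64)
        cnt = grp["pixels/count"][:].astype(np.float64)
    if cnt.size and cnt.min() < 0:
        raise ValidationError(f"{path}: negative counts")

    intra = bin_chrom_idx[b1] == bin_chrom_idx[b2]
    if (~intra).sum():
        logger.info("%s: dropped %d inter-chromosomal pixels", path, int((~intra).sum()))
    b1, b2, cnt = b1[intra], b2[intra], cnt[intra]
    out = {}
    for ci, chrom in enumerate(chrom_names):
        off = bins.offset(chrom)
        n = bins.n_bins_chrom(chrom)
        sel = bin_chrom_idx[b1] == ci
        m = sp.coo_matrix((cnt[sel], (b1[sel] - off, b2[sel] - off)), shape=(n, n))
        out[chrom] = ContactMatrix(chrom, bins, _symmetrize(m))
    return out


def write_cool(matrices: dict[str, ContactMatrix], path: str | Path) -> Path:
    """Write matrices as a minimal single-resolution cooler store."""
    path = Path(path)
    bins = next(iter(matrices.values())).bins
    table = bins.to_frame()
    chrom_idx = np.array(
        [bins.chrom_names.index(c) for c in table["chrom"]], dtype=np.int32
    )
    b1s, b2s, cs = [], [], []
    for chrom in bins.chrom_names:
        off = bins.offset(chrom)
        upper = sp.triu(matrices[chrom].counts).tocoo()
        b1s.append(upper.row.astype(np.int64) + off)
        b2s.append(upper.col.astype(np.int64) + off)
        cs.append(upper.data.astype(np.float64))
    b1 = np.concatenate(b1s) if b1s else np.array([], dtype=np.int64)
    b2 = np.concatenate(b2s) if b2s else np.array([], dtype=np.int64)
    cnt = np.concatenate(cs) if cs else np.array([], dtype=np.float64)
    order = np.lexsort((b2, b1))

    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["bin-size"] = bins.bin_size
        f.create_dataset(
            "chroms/name",
            data=np.array(bins.chrom_names, dtype=h5py.string_dtype()),
        )
        f.create_dataset("chroms/length", data=np.array(bins.chrom_lengths, np.int64))
        f.create_dataset("bins/chrom", data=chrom_idx)
        f.create_dataset("bins/start", data=table["start"].to_numpy(np.int64))
        f.create_dataset("bins/end", data=table["end"].to_numpy(np.int64))
        f.create_dataset("pixels/bin1_id", data=b1[order])
        f.create_dataset("pixels/bin2_id", data=b2[order])
        f.create_dataset("pixels/count", data=cnt[order])
    return path


def read_juicer_hic(path: str | Path, bin_size: int) -> dict[str, ContactMatrix]:
    """Read raw ("NONE"-normalized) observed counts from a Juicer .hic file.

    Requires the optional ``hicstraw`` package (install the ``hic``
    extra). The returned matrices satisfy the same contract as the
    other readers.
    """
    try:
        import hicstraw  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading .hic files requires the optional 'hicstraw' package "
            "(pip install hic-straw)"
        ) from exc

    hic = hicstraw.HiCFile(str(path))
    resolutions = [int(r) for r in hic.getResolutions()]
    if bin_size not in resolutions:
        raise ConfigurationError(
            f"{path}: resolution {bin_size} unavailable; has {sorted(resolutions)}"
        )
    chroms = [
        (c.name, int(c.length))
        for c in hic.getChromosomes()
        if c.name.lower() != "all"
    ]
    bins = GenomeBins(
        tuple(n for n, _ in chroms), tuple(l for _, l in chroms), bin_size
    )
    out = {}
    for chrom, _length in chroms:
        n = bins.n_bins_chrom(chrom)
        recs = hicstraw.straw("observed", "NONE", str(path), chrom, chrom, "BP", bin_size)
        ii = np.array([r.binX // bin_size for r in recs], dtype=np.int64)
        jj = np.array([r.binY // bin_size for r in recs], dtype=np.int64)
        cc = np.array([r.counts for r in recs], dtype=np.float64)
        m = sp.coo_matrix((cc, (ii, jj)), shape=(n, n))
        out[chrom] = ContactMatrix(chrom, bins, _symmetrize(m))
    return out


def validate_sample_sets(treatment: SampleSet, control: SampleSet) -> GenomeBins:
    """Assert both conditions share one binning scheme; return it.

    A chromosome present in one condition but not the other is a hard
    error (silent intersection could hide mislabeled inputs).
    """
    for ss in (treatment, control):
        if not ss.replicates:
            raise ValidationError(f"{ss.condition}: zero replicates")
    tb, cb = treatment.bins, control.bins
    if tb.bin_size != cb.bin_size:
        raise ConfigurationError(
            f"bin size mismatch: treatment {tb.bin_size} vs control {cb.bin_size}"
        )
    if set(tb.chrom_names) != set(cb.chrom_names):
        only_t = set(tb.chrom_names) - set(cb.chrom_names)
        only_c = set(cb.chrom_names) - set(tb.chrom_names)
        raise ValidationError(
            f"chromosome sets differ: only in treatment {sorted(only_t)}, "
            f"only in control {sorted(only_c)}"
        )
    if not tb.same_grid(cb):
        raise ValidationError("chromosome lengths/order differ between conditions")
    for ss in (treatment, control):
        for i, rep in enumerate(ss.replicates):
            if set(rep) != set(tb.chrom_names):
                raise ValidationError(
                    f"{ss.condition} replicate {i}: chromosome set differs from binning"
                )
    return tb
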
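"""Methylation quantification from targeted bisulfite amplicon reads.

Post-mapping quantification for an amplicon design: reads are assigned to the
amplicon whose bisulfite-space reference they best match, methylated (C) and
unmethylated (T) calls are counted at each CpG cytosine, sites below a
coverage cut-off (default 50x, the boundary value itself retained) are marked
missing, and the results are assembled into a samples x CpG fraction matrix.

Assignment works in bisulfite space: every reference cytosine outside CpG
context is collapsed to T (it is always converted), while CpG cytosines are
treated as C/T wildcards (their state depends on methylation).  A read is
assigned to the region of minimum Hamming distance under this matching and
discarded if that distance exceeds ``ceil(0.1 * read length)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import AmpliconPanel
from .simulate import SampleMeta, read_fastq

__all__ = [
    "MethMatrix",
    "AssignmentResult",
    "MethFileError",
    "assign_reads",
    "count_methylation",
    "filter_coverage",
    "build_matrix",
    "extract_sample",
    "read_coverage_file",
    "write_coverage_file",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = ["sample_id", "site_id", "count_methylated", "count_unmethylated"]


class MethFileError(ValueError):
    """Malformed per-CpG coverage file."""


@dataclass
class AssignmentResult:
    groups: dict[str, list[tuple[str, str]]]
    n_assigned: int
    n_discarded: int
    n_ties: int

    @property
    def n_total(self) -> int:
        return self.n_assigned + self.n_discarded


def _collapsed_reference(region_seq: str, cpg_offsets: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Bisulfite-space reference: C->T except CpG cytosines (C/T wildcard)."""
    ref = np.frombuffer(region_seq.encode(), dtype=np.uint8).copy()
    wildcard = np.zeros(ref.size, dtype=bool)
    wildcard[list(cpg_offsets)] = True
    ref[(ref == ord("C")) & ~wildcard] = ord("T")
    return ref, wildcard


def bisulfite_distance(read: str, ref: np.ndarray, wildcard: np.ndarray) -> int:
    """Hamming distance of a read against a collapsed reference.

    Positions flagged as CpG cytosines accept either C or T; any length
    difference counts as one mismatch per unmatched base.
    """
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    n = min(r.size, ref.size)
    rr, ff, ww = r[:n], ref[:n], wildcard[:n]
    ok = (rr == ff) | (ww & ((rr == ord("C")) | (rr == ord("T"))))
    return int((~ok).sum()) + abs(r.size - ref.size)


def assign_reads(
    reads: Iterable[tuple[str, str]],
    panel: AmpliconPanel,
    max_mismatch_frac: float = 0.1,
) -> AssignmentResult:
    """Assign reads to amplicons by minimum bisulfite-space Hamming distance.

    Reads whose best distance exceeds ``ceil(max_mismatch_frac * read length)``
    are discarded and counted.  Ties go to the lowest region index, with a
    warning recorded per occurrence.
    """
    if not panel.regions:
        raise ValueError("panel has no regions")
    refs = [
        _collapsed_reference(r.sequence, [s.offset for s in panel.sites_in_region(r.region_id)])
        for r in panel.regions
    ]
    groups: dict[str, list[tuple[str, str]]] = {r.region_id: [] for r in panel.regions}
    n_disc = n_ties = n_assigned = 0
    for name, seq in reads:
        dists = [bisulfite_distance(seq, ref, wc) for ref, wc in refs]
        best = min(dists)
        if best > math.ceil(max_mismatch_frac * len(seq)):
            n_disc += 1
            continue
        winners = [i for i, d in enumerate(dists) if d == best]
        if len(winners) > 1:
            n_ties += 1
            warnings.warn(
                f"read {name!r}: distance tie between regions "
                f"{[panel.regions[i].region_id for i in winners]}; "
                "assigned to the lowest index",
                stacklevel=2,
            )
        groups[panel.regions[winners[0]].region_id].append((name, seq))
        n_assigned += 1
    return AssignmentResult(groups, n_assigned, n_disc, n_ties)


def count_methylation(
    groups: dict[str, list[tuple[str, str]]],
    panel: AmpliconPanel,
    sample_id: str,
) -> pd.DataFrame:
    """Count C (methylated) / T (unmethylated) calls per CpG for one sample.

    Reads are aligned at the region start (amplicon reads are full-length by
    construction).  Bases other than C/T at a CpG position — sequencing error
    or a read too short to cover the site — leave both counts untouched.
    """
    rows = []
    for region in panel.regions:
        sites = panel.sites_in_region(region.region_id)
        reads = groups.get(region.region_id, [])
        if reads:
            maxlen = max(len(s) for _, s in reads)
            mat = np.full((len(reads), maxlen), ord("N"), dtype=np.uint8)
            for i, (_, s) in enumerate(reads):
                mat[i, : len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)
        else:
            mat = np.empty((0, 0), dtype=np.uint8)
        for site in sites:
            if mat.size and site.offset < mat.shape[1]:
                col = mat[:, site.offset]
                n_c = int((col == ord("C")).sum())
                n_t = int((col == ord("T")).sum())
            else:
                n_c = n_t = 0
            rows.append((sample_id, site.site_id, n_c, n_t))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def filter_coverage(records: pd.DataFrame, min_coverage: int = 50) -> pd.DataFrame:
    """Mark records below the coverage cut-off as missing.

    The rule is strict: coverage < ``min_coverage`` is discarded, so a site at
    exactly the cut-off is retained.  Returns a copy with a boolean
    ``missing`` column recomputed from the counts (hence idempotent, and
    monotone in ``min_coverage``).
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    out = records.copy()
    cov = out["count_methylated"] + out["count_unmethylated"]
    out["missing"] = cov < min_coverage
    return out


def extract_sample(
    reads: Iterable[tuple[str, str]] | str | Path,
    panel: AmpliconPanel,
    sample_id: str,
    max_mismatch_frac: float = 0.1,
) -> tuple[pd.DataFrame, AssignmentResult]:
    """Assign + count for one sample; ``reads`` may be a FASTQ path."""
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    assignment = assign_reads(reads, panel, max_mismatch_frac)
    records = count_methylation(assignment.groups, panel, sample_id)
    return records, assignment


@dataclass
class MethMatrix:
    """Samples x CpG methylation fractions with per-cell coverage.

    ``fraction`` holds count_methylated / coverage with NaN wherever the site
    failed the coverage filter (or was never observed) in that sample;
    ``coverage`` holds the raw read counts regardless of filtering.
    """

    fraction: pd.DataFrame
    coverage: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.coverage is not None and (
            list(self.coverage.index) != list(self.fraction.index)
            or list(self.coverage.columns) != list(self.fraction.columns)
        ):
            raise ValueError("fraction and coverage must be aligned")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fraction.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.fraction.columns)

    def restrict(self, site_ids: Sequence[str]) -> "MethMatrix":
        cov = self.coverage[list(site_ids)] if self.coverage is not None else None
        return MethMatrix(self.fraction[list(site_ids)].copy(), cov)

    def to_tsv(self, path: str | Path) -> None:
        df = self.fraction.copy()
        df.insert(0, "sample_id", df.index)
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MethMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
        if "sample_id" not in df.columns:
            raise ValueError("matrix TSV must have a sample_id first column")
        df = df.set_index("sample_id")
        df.index.name = None
        return cls(df.astype(float))


def build_matrix(
    records: pd.DataFrame,
    cohort: Sequence[SampleMeta],
    site_ids: Sequence[str],
    min_coverage: int | None = None,
) -> MethMatrix:
    """Assemble count records into a MethMatrix in cohort x panel order.

    Cells absent from ``records`` are missing with coverage 0.  If
    ``min_coverage`` is given, :func:`filter_coverage` is applied first; a
    pre-existing ``missing`` column is honoured otherwise.
    """
    recs = records
    if min_coverage is not None:
        recs = filter_coverage(recs, min_coverage)
    if recs.duplicated(subset=["sample_id", "site_id"]).any():
        dup = recs[recs.duplicated(subset=["sample_id", "site_id"], keep=False)]
        raise ValueError(
            "duplicate (sample, site) records: "
            + ", ".join(f"({r.sample_id}, {r.site_id})" for r in dup.head(5).itertuples())
        )
    sample_ids = [s.sample_id for s in cohort]
    frac = pd.DataFrame(np.nan, index=sample_ids, columns=list(site_ids), dtype=float)
    cover = pd.DataFrame(0, index=sample_ids, columns=list(site_ids), dtype=int)
    for row in recs.itertuples(index=False):
        if row.sample_id not in frac.index or row.site_id not in frac.columns:
            raise ValueError(f"record references unknown sample/site ({row.sample_id}, {row.site_id})")
        total = row.count_methylated + row.count_unmethylated
        cover.loc[row.sample_id, row.site_id] = total
        hidden = bool(getattr(row, "missing", False))
        if total > 0 and not hidden:
            frac.loc[row.sample_id, row.site_id] = row.count_methylated / total
    return MethMatrix(frac, cover)


# -- per-CpG coverage files (Bismark-coverage dialect) ---------------------

def write_coverage_file(records: pd.DataFrame, path: str | Path) -> None:
    """Write one sample's records as a Bismark-coverage-dialect TSV.

    Columns: scaffold, start, end (1-based inclusive, start == end for a CpG
    cytosine), methylation percent (6 decimals), methylated count,
    unmethylated count.  Site ids must be ``"scaffold:pos"``.
    """
    with open(path, "w") as fh:
        for row in records.itertuples(index=False):
            scaffold, pos = row.site_id.rsplit(":", 1)
            total = row.count_methylated + row.count_unmethylated
            pct = 100.0 * row.count_methylated / total if total else 0.0
            fh.write(
                f"{scaffold}\t{pos}\t{pos}\t{pct:.6f}\t"
                f"{row.count_methylated}\t{row.count_unmethylated}\n"
            )


def read_coverage_file(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read a Bismark-coverage-dialect TSV into count records.

    Site ids are reconstructed as ``"scaffold:start"``.  A malformed line
    raises :class:`MethFileError` naming the line number; a methylation
    percent inconsistent with the counts by more than 0.01 warns.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise MethFileError(f"{path}: line {lineno}: expected 6 fields, got {len(parts)}")
            scaffold, start, end, pct, n_m, n_u = parts
            try:
                start_i = int(start)
                int(end)
                pct_f = float(pct)
                n_m_i, n_u_i = int(n_m), int(n_u)
            except ValueError as exc:
                raise MethFileError(f"{path}: line {lineno}: {exc}") from None
            if n_m_i < 0 or n_u_i < 0:
                raise MethFileError(f"{path}: line {lineno}: negative count")
            total = n_m_i + n_u_i
            if total:
                expect = 100.0 * n_m_i / total
                if abs(expect - pct_f) > 0.01:
                    warnings.warn(
                        f"{path}: line {lineno}: percent {pct_f} inconsistent with "
                        f"counts ({expect:.6f})",
                        stacklevel=2,
                    )
            rows.append((sample_id, f"{scaffold}:{start_i}", n_m_i, n_u_i))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
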
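"""Targeted amplicon panel: regions, CpG site coordinates, FASTA/BED round-trip.

An :class:`AmpliconPanel` describes the targeted bisulfite PCR design: a small
set of amplified regions (one reference sequence each, placed on a named
scaffold) and the CpG dinucleotides they contain.  Synthetic panels are built
with :func:`make_panel`; real panels are loaded from a FASTA of amplicon
references plus a BED file of their genomic intervals.

Coordinate conventions: BED intervals are 0-based half-open; CpG site ids are
``"scaffold:pos"`` with ``pos`` the 1-based genomic position of the CpG
cytosine, matching the dialect of per-CpG coverage files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Region",
    "CpGSite",
    "AmpliconPanel",
    "PanelGeometryError",
    "make_panel",
    "write_panel_fasta",
    "write_panel_bed",
    "read_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class PanelGeometryError(ValueError):
    """Requested CpG layout does not fit in the region length."""


@dataclass(frozen=True)
class Region:
    """One amplicon reference sequence anchored on a scaffold."""

    region_id: str
    scaffold: str
    start: int  # 0-based genomic start
    end: int  # 0-based half-open genomic end
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"region {self.region_id}: interval length {self.end - self.start} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class CpGSite:
    """A CpG cytosine inside an amplicon region.

    ``site_id`` is ``"scaffold:pos"`` with 1-based genomic position of the C;
    ``offset`` is the 0-based position of the C within the region sequence.
    """

    site_id: str
    region_id: str
    offset: int


@dataclass
class AmpliconPanel:
    regions: list[Region]
    cpg_sites: list[CpGSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.cpg_sites]

    def region(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    def sites_in_region(self, region_id: str) -> list[CpGSite]:
        return [s for s in self.cpg_sites if s.region_id == region_id]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region_id in panel")
        sids = [s.site_id for s in self.cpg_sites]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate site_id in panel")
        by_region = {r.region_id: r for r in self.regions}
        seen: dict[str, list[tuple[int, int]]] = {}
        for r in self.regions:
            seen.setdefault(r.scaffold, []).append((r.start, r.end))
        for ivals in seen.values():
            ivals.sort()
            for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError("overlapping region intervals on one scaffold")
        for s in self.cpg_sites:
            r = by_region.get(s.region_id)
            if r is None:
                raise ValueError(f"site {s.site_id} references unknown region {s.region_id}")
            if r.sequence[s.offset : s.offset + 2] != "CG":
                raise ValueError(f"site {s.site_id} does not point at a CG dinucleotide")
        with_sites = {s.region_id for s in self.cpg_sites}
        if self.cpg_sites:
            missing = set(ids) - with_sites
            if missing:
                raise ValueError(f"regions without any CpG site: {sorted(missing)}")


def _place_offsets(rng: np.random.Generator, k: int, length: int) -> np.ndarray:
    """Choose ``k`` CpG offsets in [1, length-3], pairwise >= 2 bp apart."""
    # map "k sorted distinct values with gaps >= 2" onto "k distinct values"
    lo, hi = 1, length - 2 - (k - 1)  # candidate range before gap expansion
    n_candidates = hi - lo
    if k < 1 or n_candidates < k:
        raise PanelGeometryError(
            f"cannot place {k} CpGs >=2 bp apart in a region of {length} bp"
        )
    picks = np.sort(rng.choice(np.arange(lo, hi), size=k, replace=False))
    return picks + np.arange(k)


def _repair_background(seq: np.ndarray, placed: set[int]) -> np.ndarray:
    """Mutate the G of every unintended CG so only placed CpGs remain.

    Replacing a G by A can never create a new CG (A completes no CG pair),
    so a single left-to-right scan suffices.
    """
    is_c = seq[:-1] == b"C"
    is_g = seq[1:] == b"G"
    for i in np.nonzero(is_c & is_g)[0]:
        if int(i) not in placed:
            seq[i + 1] = b"A"
    return seq


def make_panel(
    n_regions: int,
    total_cpgs: int,
    region_length: int = 300,
    seed: int = 0,
    scaffold_prefix: str = "scaffold",
) -> AmpliconPanel:
    """Build a synthetic amplicon panel with an exact number of CpGs.

    CpGs are distributed across regions as evenly as possible (remainder
    assigned round-robin to the first regions).  Background sequence is random
    but scan-and-repaired so it contains no CG dinucleotide other than the
    placed sites: a substring scan of the emitted FASTA counts exactly
    ``total_cpgs`` occurrences of "CG".
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if total_cpgs < n_regions:
        raise ValueError("need at least one CpG per region")
    rng = np.random.default_rng(seed)
    base, rem = divmod(total_cpgs, n_regions)
    regions: list[Region] = []
    sites: list[CpGSite] = []
    for i in range(n_regions):
        k = base + (1 if i < rem else 0)
        offsets = _place_offsets(rng, k, region_length)
        seq = rng.choice(_BASES, size=region_length)
        for o in offsets:
            seq[o] = b"C"
            seq[o + 1] = b"G"
        seq = _repair_background(seq, {int(o) for o in offsets})
        scaffold = f"{scaffold_prefix}_{i + 1:02d}"
        start = int(rng.integers(100_000, 10_000_000))
        region_id = f"region_{i + 1:02d}"
        regions.append(
            Region(region_id, scaffold, start, start + region_length, seq.tobytes().decode())
        )
        for o in offsets:
            pos = start + int(o) + 1  # 1-based genomic position of the C
            sites.append(CpGSite(f"{scaffold}:{pos}", region_id, int(o)))
    return AmpliconPanel(regions, sites)


# -- serialization ---------------------------------------------------------

def write_panel_fasta(panel: AmpliconPanel, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.region_id, description="")
        for r in panel.regions
    ]
    SeqIO.write(records, str(path), "fasta")


def write_panel_bed(panel: AmpliconPanel, path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.scaffold, r.start, r.end, r.region_id) for r in panel.regions]
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def _scan_cg(sequence: str) -> Iterable[int]:
    i = sequence.find("CG")
    while i != -1:
        yield i
        i = sequence.find("CG", i + 1)


def read_panel(fasta_path: str | Path, bed_path: str | Path) -> AmpliconPanel:
    """Reconstruct a panel from its FASTA + BED; CpGs rediscovered by scanning."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["scaffold", "start", "end", "region_id"],
    )
    regions: list[Region] = []
    sites: list[CpGSite] = []
    for row in bed.itertuples(index=False):
        if row.region_id not in seqs:
            raise ValueError(f"BED region {row.region_id} missing from FASTA")
        seq = seqs[row.region_id]
        regions.append(Region(row.region_id, row.scaffold, int(row.start), int(row.end), seq))
        for o in _scan_cg(seq):
            pos = int(row.start) + o + 1
            sites.append(CpGSite(f"{row.scaffold}:{pos}", row.region_id, o))
    return AmpliconPanel(regions, sites)
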
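"""Synthetic cohorts, methylation drift, and bisulfite read simulation.

The generative model mirrors the structure of a targeted bisulfite PCR ageing
study: each CpG ``j`` has a baseline methylation fraction ``m0_j`` and a drift
slope ``s_j`` (fraction per week of age, zero at non-age-associated sites); a
tissue ``t`` scales all slopes by a rate multiplier ``r_t`` (liver = 1 by
convention, skin slower).  A sample ``i`` of age ``a_i`` then has true per-site
methylation

    p_ij = clamp(m0_j + s_j * r_t(i) * a_i + eps_ij, 0, 1),   eps ~ N(0, sigma_b^2)

Reads are simulated single-end spanning the full amplicon, so every CpG in a
region is covered by every read.  Per read, each CpG cytosine is methylated
with probability ``p_ij``; bisulfite conversion turns unmethylated cytosines
(CpG or not) into T with probability ``conversion_efficiency``; sequencing
error then substitutes each base uniformly at random.  Only the original-top
bisulfite strand is emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import AmpliconPanel

__all__ = [
    "SampleMeta",
    "DriftModel",
    "draw_cohort",
    "true_methylation",
    "simulate_reads",
    "binomial_counts",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_truth_table",
    "read_truth_table",
    "read_fastq",
    "write_fastq",
]

TISSUES = ("liver", "skin")
BATCHES = ("set1", "set2")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    age_weeks: float
    tissue: str
    batch: str

    def __post_init__(self) -> None:
        if self.age_weeks <= 0:
            raise ValueError(f"{self.sample_id}: age_weeks must be positive")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.batch not in BATCHES:
            raise ValueError(f"unknown batch {self.batch!r}")


@dataclass
class DriftModel:
    """Per-site linear methylation drift plus read-level noise parameters.

    ``m0`` and ``slope`` are aligned to the panel's ``site_ids``; ``slope`` is
    in methylation-fraction units per week.  ``tissue_rates`` scales the drift
    per tissue (liver fixed at 1).  ``sigma_b`` is per-sample-per-site
    biological noise on the methylation fraction.
    """

    site_ids: list[str]
    m0: np.ndarray
    slope: np.ndarray
    tissue_rates: dict[str, float] = field(default_factory=lambda: {"liver": 1.0, "skin": 0.6})
    sigma_b: float = 0.03
    conversion_efficiency: float = 0.99
    sequencing_error_rate: float = 0.001
    target_coverage: int = 200

    def __post_init__(self) -> None:
        self.m0 = np.asarray(self.m0, dtype=float)
        self.slope = np.asarray(self.slope, dtype=float)
        if not (len(self.site_ids) == self.m0.size == self.slope.size):
            raise ValueError("site_ids, m0 and slope must be aligned")
        if np.any((self.m0 < 0) | (self.m0 > 1)):
            raise ValueError("m0 must lie in [0, 1]")
        for name in ("conversion_efficiency", "sequencing_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability")
        if self.target_coverage < 1:
            raise ValueError("target_coverage must be >= 1")
        if any(r <= 0 for r in self.tissue_rates.values()):
            raise ValueError("tissue rate multipliers must be positive")

    @property
    def is_admp(self) -> np.ndarray:
        return self.slope != 0.0

    @classmethod
    def plant(
        cls,
        panel: AmpliconPanel,
        n_admp: int = 23,
        slope_range: tuple[float, float] = (3e-4, 6e-4),
        seed: int = 0,
        **kwargs,
    ) -> "DriftModel":
        """Plant ``n_admp`` age-drifting sites among the panel's CpGs.

        Drifting sites get a slope of random sign with magnitude uniform in
        ``slope_range`` and a baseline leaving headroom for the drift (low
        baseline for gaining sites, high for losing sites); the remaining
        sites are age-independent with baselines across the unit interval.
        """
        site_ids = panel.site_ids
        m = len(site_ids)
        if not 0 <= n_admp <= m:
            raise ValueError(f"n_admp must be in [0, {m}]")
        rng = np.random.default_rng(seed)
        m0 = rng.uniform(0.1, 0.9, size=m)
        slope = np.zeros(m)
        idx = rng.choice(m, size=n_admp, replace=False)
        mag = rng.uniform(*slope_range, size=n_admp)
        sign = rng.choice([-1.0, 1.0], size=n_admp)
        slope[idx] = sign * mag
        m0[idx] = np.where(sign > 0, rng.uniform(0.05, 0.25, n_admp), rng.uniform(0.75, 0.95, n_admp))
        return cls(site_ids=list(site_ids), m0=m0, slope=slope, **kwargs)

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_ids,
                "m0": self.m0,
                "slope": self.slope,
                "is_admp": self.is_admp,
            }
        )


def draw_cohort(
    n_samples: int,
    age_min: float,
    age_max: float,
    tissue: str = "liver",
    batch: str = "set1",
    seed: int = 0,
) -> list[SampleMeta]:
    """Draw a cohort with ages uniform on [age_min, age_max], sorted ascending."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not age_min < age_max:
        raise ValueError("age_min must be < age_max")
    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(age_min, age_max, size=n_samples))
    return [
        SampleMeta(f"{tissue}_{batch}_{i + 1:03d}", float(a), tissue, batch)
        for i, a in enumerate(ages)
    ]


def true_methylation(
    panel: AmpliconPanel,
    cohort: Sequence[SampleMeta],
    model: DriftModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample per-site methylation probabilities (samples x sites)."""
    if list(model.site_ids) != list(panel.site_ids):
        raise ValueError("drift model sites do not match panel sites")
    rng = np.random.default_rng(seed)
    ages = np.array([s.age_weeks for s in cohort])
    rates = np.array([model.tissue_rates[s.tissue] for s in cohort])
    drift = model.m0[None, :] + model.slope[None, :] * (rates * ages)[:, None]
    eps = rng.normal(0.0, model.sigma_b, size=drift.shape) if model.sigma_b > 0 else 0.0
    p = np.clip(drift + eps, 0.0, 1.0)
    return pd.DataFrame(p, index=[s.sample_id for s in cohort], columns=panel.site_ids)


# -- read-level simulation -------------------------------------------------

_B2I = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _B2I[_b] = _i
_I2B = np.frombuffer(b"ACGT", dtype=np.uint8)


def _simulate_region_reads(
    seq: str,
    cpg_offsets: np.ndarray,
    p_sites: np.ndarray,
    model: DriftModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate coverage reads for one region of one sample.

    Returns (reads as uint8 matrix coverage x L, methylated-draw counts per CpG).
    """
    cov = model.target_coverage
    ref = np.frombuffer(seq.encode(), dtype=np.uint8)
    L = ref.size
    reads = np.tile(ref, (cov, 1))
    c_cols = np.nonzero(ref == ord("C"))[0]
    cpg_set = set(int(o) for o in cpg_offsets)
    noncpg_c = np.array([c for c in c_cols if c not in cpg_set], dtype=int)

    # CpG cytosines: methylated per read with probability p; unmethylated ones
    # convert C->T with probability conversion_efficiency.
    n_meth = np.zeros(len(cpg_offsets), dtype=int)
    for k, (o, p) in enumerate(zip(cpg_offsets, p_sites)):
        meth = rng.random(cov) < p
        n_meth[k] = int(meth.sum())
        convert = (~meth) & (rng.random(cov) < model.conversion_efficiency)
        reads[convert, int(o)] = ord("T")

    # Non-CpG cytosines are always unmethylated.
    if noncpg_c.size:
        convert = rng.random((cov, noncpg_c.size)) < model.conversion_efficiency
        cols = np.broadcast_to(noncpg_c, (cov, noncpg_c.size))
        reads[np.nonzero(convert)[0], cols[convert]] = ord("T")

    # Uniform substitution error over the whole read matrix.
    if model.sequencing_error_rate > 0:
        err = rng.random((cov, L)) < model.sequencing_error_rate
        ii, jj = np.nonzero(err)
        if ii.size:
            shift = rng.integers(1, 4, size=ii.size).astype(np.uint8)
            reads[ii, jj] = _I2B[(_B2I[reads[ii, jj]] + shift) % 4]
    return reads, n_meth


def simulate_reads(
    panel: AmpliconPanel,
    cohort: Sequence[SampleMeta],
    probs: pd.DataFrame,
    model: DriftModel,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Simulate per-sample FASTQ reads and the generator's own truth ledger.

    Returns ``(reads, truth)`` where ``reads[sample_id]`` is a list of
    ``(name, sequence)`` and ``truth`` records, per (sample, site), the number
    of per-read methylated draws and the number of reads — the exact counts a
    perfect extractor must recover when conversion is complete and the error
    rate is zero.  If ``outdir`` is given, one ``<sample_id>.fastq`` per sample
    is also written there.
    """
    if list(probs.columns) != list(panel.site_ids):
        raise ValueError("probs columns must match panel site order")
    if list(probs.index) != [s.sample_id for s in cohort]:
        raise ValueError("probs rows must match cohort order")
    rng = np.random.default_rng(seed)
    out: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    for sample in cohort:
        reads_for_sample: list[tuple[str, str]] = []
        for region in panel.regions:
            sites = panel.sites_in_region(region.region_id)
            offsets = np.array([s.offset for s in sites], dtype=int)
            p_sites = probs.loc[sample.sample_id, [s.site_id for s in sites]].to_numpy()
            mat, n_meth = _simulate_region_reads(region.sequence, offsets, p_sites, model, rng)
            for r in range(mat.shape[0]):
                name = f"{sample.sample_id}|{region.region_id}|r{r:05d}"
                reads_for_sample.append((name, mat[r].tobytes().decode()))
            for s, nm in zip(sites, n_meth):
                truth_rows.append(
                    (sample.sample_id, s.site_id, int(nm), model.target_coverage)
                )
        out[sample.sample_id] = reads_for_sample
        if outdir is not None:
            write_fastq(reads_for_sample, Path(outdir) / f"{sample.sample_id}.fastq")
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "site_id", "n_meth_drawn", "n_reads"])
    return out, truth


def binomial_counts(
    probs: pd.DataFrame,
    coverage: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial methylated-read counts at uniform coverage, bypassing reads.

    Statistically equivalent to simulating error-free, fully converted reads
    and extracting them; used where only the count-level behaviour matters.
    Returns (n_meth, coverage) DataFrames shaped like ``probs``.
    """
    rng = np.random.default_rng(seed)
    n_meth = rng.binomial(coverage, probs.to_numpy())
    cov = pd.DataFrame(coverage, index=probs.index, columns=probs.columns)
    return pd.DataFrame(n_meth, index=probs.index, columns=probs.columns), cov


# -- plain-text I/O --------------------------------------------------------

def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) reads as Phred+33 FASTQ with uniform 'I' quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    with open(path) as fh:
        return [(name, seq) for name, seq, _qual in FastqGeneralIterator(fh)]


def write_sample_sheet(cohort: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.age_weeks, s.tissue, s.batch) for s in cohort],
        columns=["sample_id", "age_weeks", "tissue", "batch"],
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "age_weeks", "tissue", "batch"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    ages = pd.to_numeric(df["age_weeks"], errors="coerce")
    bad = df.index[ages.isna()]
    if len(bad):
        row = int(bad[0])
        raise ValueError(
            f"sample sheet row {row + 2}: non-numeric or missing age "
            f"for sample {df.loc[row, 'sample_id']!r}"
        )
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dups}")
    return [
        SampleMeta(str(r.sample_id), float(a), str(r.tissue), str(r.batch))
        for r, a in zip(df.itertuples(index=False), ages)
    ]


def write_truth_table(model: DriftModel, path: str | Path) -> None:
    model.truth_table().to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
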
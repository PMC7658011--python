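"""Domain types shared across the pipeline.

Tabular payloads (counts, expression values) live in pandas objects; the
wrapper classes add the experiment-design metadata and the validation the
downstream statistics rely on (ordered generations, unique gene ids,
positive library sizes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("symbiotrend")

HOST = "host"
SYMBIONT = "symbiont"

EXPRESSION_SCALES = ("rpm", "log2_rpm", "log2_rpm_median_centered")


@dataclass(frozen=True)
class SampleDesign:
    """Design label of one RNA-seq sample: which generation, which replicate."""

    sample_id: str
    generation: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate must be >= 1, got {self.replicate}"
            )


class DesignTable:
    """Ordered collection of :class:`SampleDesign` with a declared generation order.

    Generation order is explicit (e.g. ``["G2", "G6", "G9"]``), never lexical:
    lexical sorting puts G10 before G2.
    """

    def __init__(self, designs: list[SampleDesign], generation_order: list[str]):
        if len(set(generation_order)) != len(generation_order):
            raise ValueError("generation_order contains duplicates")
        seen_pairs = set()
        for d in designs:
            if d.generation not in generation_order:
                raise ValueError(
                    f"sample {d.sample_id!r}: generation {d.generation!r} not in "
                    f"declared order {generation_order}"
                )
            pair = (d.generation, d.replicate)
            if pair in seen_pairs:
                raise ValueError(f"duplicate (generation, replicate) pair {pair}")
            seen_pairs.add(pair)
        present = {d.generation for d in designs}
        missing = [g for g in generation_order if g not in present]
        if missing:
            raise ValueError(f"generations declared but without samples: {missing}")
        ids = [d.sample_id for d in designs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in design")
        self.designs = list(designs)
        self.generation_order = list(generation_order)
        self._by_id = {d.sample_id: d for d in designs}

    @property
    def sample_ids(self) -> list[str]:
        return [d.sample_id for d in self.designs]

    def __getitem__(self, sample_id: str) -> SampleDesign:
        return self._by_id[sample_id]

    def __len__(self) -> int:
        return len(self.designs)

    def samples_by_generation(self) -> dict[str, list[str]]:
        """Sample ids per generation, in declared generation order."""
        out: dict[str, list[str]] = {g: [] for g in self.generation_order}
        for d in self.designs:
            out[d.generation].append(d.sample_id)
        return out


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with organism labels and a design.

    ``counts`` is a genes-by-samples DataFrame of non-negative integers;
    ``organism`` maps every gene id to ``"host"`` or ``"symbiont"``.
    """

    counts: pd.DataFrame
    organism: pd.Series
    design: DesignTable

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            arr = self.counts.to_numpy()
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            bad = self.counts.stack()
            bad = bad[bad < 0]
            gene, sample = bad.index[0]
            raise ValueError(
                f"negative count {bad.iloc[0]} at gene {gene!r}, sample {sample!r}"
            )
        missing_design = [s for s in self.counts.columns if s not in self.design.sample_ids]
        if missing_design:
            raise ValueError(f"sample columns missing from design: {missing_design}")
        self.organism = self.organism.reindex(self.counts.index)
        if self.organism.isna().any():
            defaulted = self.organism.index[self.organism.isna()].tolist()
            logger.warning(
                "organism map missing for %d genes (e.g. %s); defaulting to host",
                len(defaulted), defaulted[:3],
            )
            self.organism = self.organism.fillna(HOST)
        bad_org = set(self.organism.unique()) - {HOST, SYMBIONT}
        if bad_org:
            raise ValueError(f"unknown organism labels: {sorted(bad_org)}")
        lib = self.library_sizes()
        if (lib <= 0).any():
            empty = lib.index[lib <= 0].tolist()
            raise ValueError(f"zero library size in samples: {empty}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        """Per-sample total read count over all genes (host + symbiont)."""
        return self.counts.sum(axis=0)

    def subset_organism(self, organism: str) -> pd.DataFrame:
        return self.counts.loc[self.organism == organism]


@dataclass
class ExpressionMatrix:
    """Normalized expression values with explicit provenance of the scale."""

    values: pd.DataFrame
    design: DesignTable
    scale: str
    pseudocount: float = 0.0
    tmm_factors: pd.Series | None = None
    organism: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in EXPRESSION_SCALES:
            raise ValueError(f"scale must be one of {EXPRESSION_SCALES}, got {self.scale!r}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.scale == "rpm" and (self.values.to_numpy() < 0).any():
            raise ValueError("rpm-scale values must be non-negative")
        if self.tmm_factors is not None and (self.tmm_factors <= 0).any():
            raise ValueError("TMM factors must be positive")


@dataclass(frozen=True)
class SectionMeasurement:
    """Raw morphometry of one leaf-sheath cross section.

    ``diameters_um`` holds the per-hypha diameter measurements (a subsample of
    40-50 hyphae when the section holds more); area conversion happens
    downstream in one place.
    """

    genotype_id: str
    generation: str
    tiller_id: str
    section_index: int
    hyphal_count: int
    diameters_um: tuple[float, ...]
    vascular_hyphae: int

    def __post_init__(self) -> None:
        ident = f"{self.genotype_id}/{self.tiller_id}/section {self.section_index}"
        if not 1 <= self.section_index <= 3:
            raise ValueError(f"{ident}: section_index must be in 1..3")
        if self.hyphal_count < 0:
            raise ValueError(f"{ident}: negative hyphal_count")
        if self.vascular_hyphae < 0 or self.vascular_hyphae > self.hyphal_count:
            raise ValueError(
                f"{ident}: vascular_hyphae {self.vascular_hyphae} exceeds "
                f"hyphal_count {self.hyphal_count}"
            )
        for d in self.diameters_um:
            if not (math.isfinite(d) and d > 0):
                raise ValueError(f"{ident}: diameters must be finite and > 0, got {d}")
        if self.hyphal_count > 0 and not self.diameters_um:
            logger.warning("%s: no diameters recorded for %d hyphae", ident, self.hyphal_count)


@dataclass(frozen=True)
class TransmissionRecord:
    """Infection-testing outcome for one generation of the maintenance program."""

    generation: int
    n_tested: int
    n_infected: int
    selected: bool = True

    def __post_init__(self) -> None:
        if self.n_tested < 1:
            raise ValueError(f"generation {self.generation}: n_tested must be >= 1")
        if not 0 <= self.n_infected <= self.n_tested:
            raise ValueError(
                f"generation {self.generation}: n_infected {self.n_infected} outside "
                f"[0, {self.n_tested}]"
            )

    @property
    def rate(self) -> float:
        return self.n_infected / self.n_tested


@dataclass(frozen=True)
class TillerRecord:
    """Tiller count of one genotype on one observation day."""

    genotype_id: str
    generation: str
    day: int
    tiller_count: int

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"{self.genotype_id}: negative day")
        if self.tiller_count < 1:
            raise ValueError(f"{self.genotype_id} day {self.day}: tiller_count must be >= 1")


def check_tiller_monotone(records: list[TillerRecord]) -> None:
    """Warn (never fail) when a genotype's tiller counts decrease over days."""
    by_geno: dict[str, list[TillerRecord]] = {}
    for r in records:
        by_geno.setdefault(r.genotype_id, []).append(r)
    for geno, recs in by_geno.items():
        recs = sorted(recs, key=lambda r: r.day)
        for prev, cur in zip(recs, recs[1:]):
            if cur.tiller_count < prev.tiller_count:
                logger.warning(
                    "genotype %s: tiller count drops from %d (day %d) to %d (day %d)",
                    geno, prev.tiller_count, prev.day, cur.tiller_count, cur.day,
                )
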
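"""Readers and writers for the plain-text input formats.

All tables are UTF-8 with a header row, '.' decimal separator; TSV for the
count matrix and its design, CSV for phenotype tables. The semicolon is the
list separator inside the per-section ``diameters`` field.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    HOST,
    CountMatrix,
    DesignTable,
    SampleDesign,
    SectionMeasurement,
    TillerRecord,
    TransmissionRecord,
    check_tiller_monotone,
)

logger = logging.getLogger("symbiotrend")

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def read_design(path: str | Path) -> DesignTable:
    """Read a sample-design TSV (columns: sample_id, generation, replicate).

    Generation order is the order of first appearance in the file, not a
    lexical sort.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "generation", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design file missing columns {sorted(missing)}")
    order: list[str] = []
    designs = []
    for _, row in df.iterrows():
        gen = str(row["generation"])
        if gen not in order:
            order.append(gen)
        designs.append(
            SampleDesign(str(row["sample_id"]), gen, int(row["replicate"]))
        )
    return DesignTable(designs, order)


def read_organisms(path: str | Path) -> pd.Series:
    """Read a gene -> organism TSV (columns: gene_id, organism)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "organism"} <= set(df.columns):
        raise ValueError(f"{path}: organism map needs columns gene_id, organism")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids in organism map")
    return pd.Series(df["organism"].values, index=df["gene_id"].values, name="organism")


def read_counts(
    path: str | Path,
    design_path: str | Path,
    organism_path: str | Path | None = None,
) -> CountMatrix:
    """Read a gene x sample count TSV plus its design and organism map.

    The count file has gene ids in the first column and one column per
    sample. Genes absent from the organism map default to host with a logged
    warning; negative or non-integer counts are hard errors naming the cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.stack()[pd.to_numeric(df.stack(), errors="coerce").isna()]
        gene, sample = bad.index[0]
        raise ValueError(f"{path}: non-numeric count {bad.iloc[0]!r} at gene {gene!r}, sample {sample!r}")
    if np.any(arr < 0) or not np.all(np.equal(np.mod(arr, 1), 0)):
        flat = df.stack()
        bad = flat[(flat < 0) | (np.mod(flat, 1) != 0)]
        gene, sample = bad.index[0]
        raise ValueError(
            f"{path}: invalid count {bad.iloc[0]} at gene {gene!r}, sample {sample!r} "
            "(counts must be non-negative integers)"
        )
    design = read_design(design_path)
    if organism_path is not None:
        organism = read_organisms(organism_path)
    else:
        logger.warning("no organism map given; labelling all genes host")
        organism = pd.Series(HOST, index=df.index, name="organism")
    cm = CountMatrix(counts=df.astype(np.int64), organism=organism, design=design)
    logger.info(
        "read counts: %d genes x %d samples from %s", len(cm.gene_ids), len(cm.sample_ids), path
    )
    return cm


def write_counts(cm: CountMatrix, path: str | Path, design_path: str | Path,
                 organism_path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in cm.design.designs],
            "generation": [d.generation for d in cm.design.designs],
            "replicate": [d.replicate for d in cm.design.designs],
        }
    ).to_csv(design_path, sep="\t", index=False)
    cm.organism.rename_axis("gene_id").rename("organism").to_frame().to_csv(
        organism_path, sep="\t"
    )


def read_sections(path: str | Path) -> list[SectionMeasurement]:
    """Read per-section morphometry CSV.

    Columns: genotype_id, generation, tiller_id, section_index, hyphal_count,
    diameters (semicolon-separated um values), vascular_hyphae.
    """
    df = pd.read_csv(path, dtype=str)
    required = {
        "genotype_id", "generation", "tiller_id", "section_index",
        "hyphal_count", "diameters", "vascular_hyphae",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sections file missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        raw = row["diameters"]
        if pd.isna(raw) or str(raw).strip() == "":
            diam: tuple[float, ...] = ()
        else:
            diam = tuple(float(x) for x in str(raw).split(";") if x.strip() != "")
        records.append(
            SectionMeasurement(
                genotype_id=str(row["genotype_id"]),
                generation=str(row["generation"]),
                tiller_id=str(row["tiller_id"]),
                section_index=int(row["section_index"]),
                hyphal_count=int(row["hyphal_count"]),
                diameters_um=diam,
                vascular_hyphae=int(row["vascular_hyphae"]),
            )
        )
    logger.info("read %d section measurements from %s", len(records), path)
    return records


def write_sections(records: list[SectionMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        {
            "genotype_id": [r.genotype_id for r in records],
            "generation": [r.generation for r in records],
            "tiller_id": [r.tiller_id for r in records],
            "section_index": [r.section_index for r in records],
            "hyphal_count": [r.hyphal_count for r in records],
            "diameters": [";".join(repr(d) for d in r.diameters_um) for r in records],
            "vascular_hyphae": [r.vascular_hyphae for r in records],
        }
    ).to_csv(path, index=False)


def read_transmission(path: str | Path) -> list[TransmissionRecord]:
    """Read per-generation infection-testing CSV.

    Columns: generation, n_tested, n_infected, selected (true/false).
    """
    df = pd.read_csv(path, dtype=str)
    required = {"generation", "n_tested", "n_infected", "selected"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: transmission file missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        sel = str(row["selected"]).strip().lower()
        if sel not in _TRUE | _FALSE:
            raise ValueError(f"{path}: unrecognized selected flag {row['selected']!r}")
        records.append(
            TransmissionRecord(
                generation=int(row["generation"]),
                n_tested=int(row["n_tested"]),
                n_infected=int(row["n_infected"]),
                selected=sel in _TRUE,
            )
        )
    return records


def write_transmission(records: list[TransmissionRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "generation": [r.generation for r in records],
            "n_tested": [r.n_tested for r in records],
            "n_infected": [r.n_infected for r in records],
            "selected": [str(r.selected).lower() for r in records],
        }
    ).to_csv(path, index=False)


def read_tillering(path: str | Path) -> list[TillerRecord]:
    """Read tiller-count time-series CSV (genotype_id, generation, day, tiller_count)."""
    df = pd.read_csv(path, dtype=str)
    required = {"genotype_id", "generation", "day", "tiller_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: tillering file missing columns {sorted(missing)}")
    records = [
        TillerRecord(
            genotype_id=str(row["genotype_id"]),
            generation=str(row["generation"]),
            day=int(row["day"]),
            tiller_count=int(row["tiller_count"]),
        )
        for _, row in df.iterrows()
    ]
    check_tiller_monotone(records)
    return records


def write_tillering(records: list[TillerRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "genotype_id": [r.genotype_id for r in records],
            "generation": [r.generation for r in records],
            "day": [r.day for r in records],
            "tiller_count": [r.tiller_count for r in records],
        }
    ).to_csv(path, index=False)


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain list of gene ids, one per line (e.g. a DE-significant list)."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}
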
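"""Readers and writers for the pipeline's TSV / FASTA dialects."""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ld import CultureCount, FluctuationAssay, RateEstimate

__all__ = [
    "read_assay_tsv",
    "write_assay_tsv",
    "write_rate_report",
    "read_pcr_table",
    "read_fasta",
    "write_fasta",
    "load_published_rates",
    "load_interaction_pairs",
    "load_rounding_exceptions",
]

ASSAY_COLUMNS = [
    "genotype",
    "reporter",
    "culture_id",
    "mutants",
    "total_cells",
    "plated_fraction_sel",
    "plated_fraction_tot",
]


def read_assay_tsv(path: str | Path) -> list[FluctuationAssay]:
    """Read per-culture fluctuation counts grouped into assays.

    Expected columns: ``genotype reporter culture_id mutants total_cells
    plated_fraction_sel plated_fraction_tot``; missing plating fractions
    default to 1.0 (whole culture plated).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"genotype", "reporter", "culture_id", "mutants", "total_cells"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"assay table {path} lacks columns {sorted(missing)}")
    for col in ("plated_fraction_sel", "plated_fraction_tot"):
        if col not in df.columns:
            df[col] = 1.0
        df[col] = df[col].fillna(1.0)
    assays = []
    for (genotype, reporter), group in df.groupby(["genotype", "reporter"], sort=False):
        cultures = tuple(
            CultureCount(
                culture_id=str(row.culture_id),
                r=int(row.mutants),
                n_t=float(row.total_cells),
                plated_fraction_selective=float(row.plated_fraction_sel),
                plated_fraction_total=float(row.plated_fraction_tot),
            )
            for row in group.itertuples()
        )
        assays.append(
            FluctuationAssay(genotype=str(genotype), reporter=str(reporter), cultures=cultures)
        )
    return assays


def write_assay_tsv(assays: Iterable[FluctuationAssay], path: str | Path) -> None:
    rows = [
        {
            "genotype": a.genotype,
            "reporter": a.reporter,
            "culture_id": c.culture_id,
            "mutants": c.r,
            "total_cells": c.n_t,
            "plated_fraction_sel": c.plated_fraction_selective,
            "plated_fraction_tot": c.plated_fraction_total,
        }
        for a in assays
        for c in a.cultures
    ]
    pd.DataFrame(rows, columns=ASSAY_COLUMNS).to_csv(path, sep="\t", index=False)


def rate_report_frame(
    estimates: Iterable[tuple[str, str, RateEstimate]]
) -> pd.DataFrame:
    """Rate report rows: one (genotype, reporter, estimate) per line."""
    rows = []
    for genotype, reporter, est in estimates:
        rows.append(
            {
                "genotype": genotype,
                "reporter": reporter,
                "method": est.method,
                "rate": est.rate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "m": est.m,
                "n_cultures": est.n_cultures,
                "upper_bound": int(est.is_upper_bound),
            }
        )
    return pd.DataFrame(rows)


def write_rate_report(
    estimates: Iterable[tuple[str, str, RateEstimate]], path: str | Path
) -> None:
    rate_report_frame(estimates).to_csv(path, sep="\t", index=False)


def read_pcr_table(path: str | Path) -> pd.DataFrame:
    """PCR screening table: ``isolate can1_amplified pol2_amplified``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"isolate", "can1_amplified", "pol2_amplified"}
    if required - set(df.columns):
        raise ValueError(f"PCR table {path} lacks columns {sorted(required - set(df.columns))}")
    for col in ("can1_amplified", "pol2_amplified"):
        df[col] = df[col].astype(bool)
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _packaged(name: str):
    return importlib.resources.files("fluxmut.data").joinpath(name)


def load_published_rates() -> pd.DataFrame:
    """Packaged transcription of the published mutant-panel rate tables."""
    with importlib.resources.as_file(_packaged("published_rates.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    df["upper_bound"] = df["upper_bound"].astype(bool)
    return df


def load_interaction_pairs() -> pd.DataFrame:
    with importlib.resources.as_file(_packaged("interaction_pairs.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    df["components"] = df["components"].map(lambda s: [c.strip() for c in s.split("+")])
    return df


def load_rounding_exceptions() -> pd.DataFrame:
    """Cells whose printed relative rate cannot be recovered from the
    printed absolute rates under the documented rounding convention (the
    published values were evidently derived from unrounded rates)."""
    with importlib.resources.as_file(_packaged("rounding_exceptions.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")
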
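"""End-to-end orchestration: rates, relatives, interactions, reconciliation.

The rate stage turns per-culture count tables into one rate estimate per
(genotype, reporter): the Drake median estimator for the forward/reversion
reporters (CAN1, his7-2) and the MSS maximum-likelihood estimator for the
rare-event GCR assay.  The relative stage divides each genotype's rate by
its wild type; the interaction stage classifies combined mutants against
their components; and the reconciliation stage recomputes every relative
rate in the packaged published-rate tables from the printed absolute
rates and reports cell-by-cell agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as fio
from .ld import FluctuationAssay, RateEstimate, drake_median_rate, mss_mle
from .rates import (
    InvalidComparisonError,
    classify_interaction,
    printed_relative,
    round_sig,
)

__all__ = [
    "RunConfig",
    "run_rate_stage",
    "relative_rate_frame",
    "interaction_frame",
    "reproduce_tables",
]

log = logging.getLogger("fluxmut")

#: Estimator used for each reporter unless overridden in RunConfig.
DEFAULT_METHODS = {"CAN1": "drake_median", "his7-2": "drake_median", "GCR": "mss_mle"}


@dataclass
class RunConfig:
    """Settings shared by the pipeline stages."""

    wild_type: str = "wild type"
    tolerance_factor: float = 1.5
    complex_window: int = 10
    sig_figs: int = 2
    seed: int = 0
    methods: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_METHODS))


def _estimate(assay: FluctuationAssay, method: str) -> RateEstimate:
    if method == "mss_mle":
        return mss_mle(assay)
    if method == "drake_median":
        return drake_median_rate(assay)
    if method == "drake_pooled":
        return drake_median_rate(assay, pooled=True)
    raise ValueError(f"unknown method {method!r}")


def run_rate_stage(
    assays: list[FluctuationAssay], config: RunConfig | None = None
) -> pd.DataFrame:
    """One rate estimate per (genotype, reporter).

    Assays whose estimation fails are logged and skipped; an empty input
    is a hard error.
    """
    config = config or RunConfig()
    if not assays:
        raise ValueError("no assays to estimate")
    rows = []
    for assay in assays:
        method = config.methods.get(assay.reporter, "drake_median")
        try:
            est = _estimate(assay, method)
        except Exception as exc:  # keep the run going, record the failure
            log.error("estimation failed for %s/%s: %s", assay.genotype, assay.reporter, exc)
            continue
        rows.append((assay.genotype, assay.reporter, est))
    return fio.rate_report_frame(rows)


def relative_rate_frame(
    report: pd.DataFrame, wild_type: str, sig_figs: int = 2
) -> pd.DataFrame:
    """Attach relative rates (vs the named wild type) to a rate report."""
    out = report.copy()
    rel_rounded, rel_raw = [], []
    for _, row in out.iterrows():
        wt = report[
            (report["genotype"] == wild_type) & (report["reporter"] == row["reporter"])
        ]
        if wt.empty:
            raise InvalidComparisonError(
                f"no wild-type rate for reporter {row['reporter']}"
            )
        q = row["rate"] / float(wt["rate"].iloc[0])
        rel_raw.append(q)
        rel_rounded.append(round_sig(q, sig_figs))
    out["relative_rate"] = rel_rounded
    out["relative_rate_unrounded"] = rel_raw
    return out


def interaction_frame(
    relatives: pd.DataFrame, pairs: pd.DataFrame, tolerance_factor: float = 1.5
) -> pd.DataFrame:
    """Classify every combined mutant present in the relative-rate table.

    ``relatives`` must carry genotype, reporter and relative_rate columns;
    ``pairs`` maps each combined genotype to its component genotypes.
    """
    rows = []
    for _, pair in pairs.iterrows():
        for reporter, group in relatives.groupby("reporter"):
            lookup = dict(zip(group["genotype"], group["relative_rate"]))
            if pair["combined"] not in lookup:
                continue
            if not all(c in lookup for c in pair["components"]):
                continue
            singles = [float(lookup[c]) for c in pair["components"]]
            combined = float(lookup[pair["combined"]])
            try:
                call = classify_interaction(singles, combined, tolerance_factor)
            except Exception as exc:
                log.warning("skipping %s/%s: %s", pair["combined"], reporter, exc)
                continue
            rows.append(
                {
                    "combined": pair["combined"],
                    "components": " + ".join(pair["components"]),
                    "reporter": reporter,
                    "single_relatives": ",".join(f"{s:g}" for s in singles),
                    "combined_relative": combined,
                    "sum_expectation": call.sum_expectation,
                    "product_expectation": call.product_expectation,
                    "category": call.category,
                }
            )
    return pd.DataFrame(rows)


def reproduce_tables(
    published: pd.DataFrame | None = None,
    pairs: pd.DataFrame | None = None,
    exceptions: pd.DataFrame | None = None,
    tolerance_factor: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Recompute the published relative rates and interaction calls.

    Every relative rate is recomputed as the printed absolute rate divided
    by the printed wild-type rate of the same background and reporter,
    rendered with the documented printing convention, and compared with
    the printed relative.  Cells listed in the packaged exception file are
    those whose printed relatives were evidently derived from unrounded
    absolute rates; they are reported as documented mismatches rather than
    failures.  Returns the reconciliation table, the interaction-call
    table, and summary statistics.
    """
    published = published if published is not None else fio.load_published_rates()
    pairs = pairs if pairs is not None else fio.load_interaction_pairs()
    exceptions = exceptions if exceptions is not None else fio.load_rounding_exceptions()
    exc_keys = set(
        zip(exceptions["table"], exceptions["genotype"], exceptions["reporter"])
    )
    rows = []
    for _, row in published.iterrows():
        wt = published[
            (published["genotype"] == row["background"])
            & (published["reporter"] == row["reporter"])
        ]
        if wt.empty:
            continue
        q = row["rate_1e8"] / float(wt["rate_1e8"].iloc[0])
        computed = printed_relative(q)
        printed = float(row["printed_relative"])
        key = (row["table"], row["genotype"], row["reporter"])
        if bool(row["upper_bound"]):
            status = "upper_bound"
        elif computed == printed:
            status = "match"
        elif key in exc_keys:
            status = "documented_mismatch"
        else:
            status = "mismatch"
        rows.append(
            {
                "table": row["table"],
                "genotype": row["genotype"],
                "reporter": row["reporter"],
                "rate_1e8": row["rate_1e8"],
                "computed_relative": computed,
                "printed_relative": printed,
                "unrounded": q,
                "status": status,
            }
        )
    recon = pd.DataFrame(rows)
    relatives = recon.rename(columns={"printed_relative": "relative_rate"})[
        ["genotype", "reporter", "relative_rate"]
    ]
    interactions = interaction_frame(relatives, pairs, tolerance_factor)
    comparable = recon[recon["status"] != "upper_bound"]
    n_match = int((comparable["status"] == "match").sum())
    n_documented = int((comparable["status"] == "documented_mismatch").sum())
    summary = {
        "n_cells": int(len(comparable)),
        "n_match": n_match,
        "n_documented_mismatch": n_documented,
        "n_unexplained_mismatch": int((comparable["status"] == "mismatch").sum()),
        "match_fraction": n_match / len(comparable),
        "match_fraction_excluding_documented": (
            n_match / max(len(comparable) - n_documented, 1)
        ),
    }
    return recon, interactions, summary
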
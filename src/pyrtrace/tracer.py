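"""Atom percent excess, fractional contribution and carbon-source partitioning.

For a corrected MID M0..Mn over n labelable carbons:

    APE = sum_{i=1..n} Mi * i / n

is the average fractional 13C labelling of those carbons.  The fractional
contribution (FC) of a precursor to a product is the ratio of their APEs.
Blood glucose carbon is partitioned using the C4-C6 glucose fragment (the
triose-derived half of the molecule):

    FC(glucose <- gavaged tracer)  = APE_glc / APE_tracer
    FC(glucose <- blood pyruvate)  = APE_glc / APE_pyruvate
    FC(glucose <- non-pyruvate)    = 1 - FC(glucose <- blood pyruvate)

and absolute attributions (mg/dL) are FC x blood glucose concentration,
with the endogenous-pyruvate share being the difference between the
blood-pyruvate and gavaged-tracer attributions.  These indices quantify
carbon provenance at the sampling time point, not metabolic rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .midcorr import MID

__all__ = [
    "APEValue",
    "FCResult",
    "NormalizedAbundance",
    "SourcePartition",
    "ape",
    "fractional_contribution",
    "glucose_source_partition",
    "metabolite_source_partition",
    "partition_table",
    "semiquant_normalize",
    "DEFAULT_TRACER_ENRICHMENT",
]

#: Gavage solution tracer content: fraction of molecules fully (M+3)
#: 13C-labelled.  Configurable in every entry point that uses it.
DEFAULT_TRACER_ENRICHMENT = 0.40


@dataclass(frozen=True)
class APEValue:
    """Atom percent excess of one metabolite (fraction in [0, 1])."""

    value: float
    metabolite: str = ""
    n: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"APE {self.value} outside [0, 1]")


@dataclass(frozen=True)
class FCResult:
    """Fractional contribution of a carbon source to a metabolite."""

    value: float
    metabolite: str = ""
    source: str = ""
    exceeds_one: bool = False


@dataclass(frozen=True)
class SourcePartition:
    """Attribution of a metabolite pool to gavaged-tracer, endogenous-pyruvate
    and non-pyruvate carbon sources, fractional and absolute."""

    concentration: float
    ape_metabolite: float
    ape_blood_pyruvate: float
    ape_tracer: float
    fc_from_gavaged: float
    fc_from_blood_pyruvate: float
    fc_from_non_pyruvate: float
    abs_from_gavaged: float
    abs_from_endogenous_pyruvate: float
    abs_from_non_pyruvate: float
    negative_non_pyruvate: bool = False


@dataclass(frozen=True)
class NormalizedAbundance:
    """Semi-quantitative relative abundance (IS- and weight-normalised)."""

    value: float
    sample_id: str = ""
    metabolite: str = ""


def ape(mid: MID, metabolite: str = "") -> APEValue:
    """Atom percent excess of a corrected MID: sum(Mi * i) / n."""
    if mid.n < 1:
        raise ValueError("APE undefined for n = 0 labelable carbons")
    i = np.arange(mid.n + 1)
    value = float((mid.fractions * i).sum() / mid.n)
    return APEValue(min(value, 1.0), metabolite=metabolite, n=mid.n)


def fractional_contribution(ape_met: APEValue,
                            ape_source: APEValue) -> FCResult:
    """FC of a source to a metabolite: APE_metabolite / APE_source."""
    if ape_source.value <= 0:
        raise ZeroDivisionError(
            f"FC undefined: source {ape_source.metabolite or 'APE'} has "
            "zero atom percent excess"
        )
    value = ape_met.value / ape_source.value
    return FCResult(value, metabolite=ape_met.metabolite,
                    source=ape_source.metabolite, exceeds_one=value > 1.0)


def metabolite_source_partition(ape_met: APEValue, ape_pyr: APEValue,
                                ape_tracer: float = DEFAULT_TRACER_ENRICHMENT,
                                concentration: float = 0.0,
                                clip_negative: bool = False) -> SourcePartition:
    """Partition any metabolite pool into gavaged / endogenous-pyruvate /
    non-pyruvate carbon sources.

    ``concentration`` is in whatever unit the metabolite is quantified in
    (mg/dL for glucose, mM for lactate); absolute attributions inherit it.
    A non-pyruvate fraction driven negative by measurement noise is reported
    as-is and flagged unless ``clip_negative`` is set.
    """
    if ape_tracer <= 0:
        raise ValueError("tracer enrichment must be positive")
    if ape_pyr.value <= 0:
        raise ZeroDivisionError("blood pyruvate APE must be positive")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    fc_gav = ape_met.value / ape_tracer
    fc_bp = ape_met.value / ape_pyr.value
    fc_np = 1.0 - fc_bp
    negative = fc_np < 0
    if negative and clip_negative:
        fc_np = 0.0
    return SourcePartition(
        concentration=concentration,
        ape_metabolite=ape_met.value,
        ape_blood_pyruvate=ape_pyr.value,
        ape_tracer=ape_tracer,
        fc_from_gavaged=fc_gav,
        fc_from_blood_pyruvate=fc_bp,
        fc_from_non_pyruvate=fc_np,
        abs_from_gavaged=fc_gav * concentration,
        abs_from_endogenous_pyruvate=(fc_bp - fc_gav) * concentration,
        abs_from_non_pyruvate=fc_np * concentration,
        negative_non_pyruvate=negative,
    )


def glucose_source_partition(ape_glc: APEValue, ape_pyr: APEValue,
                             ape_tracer: float = DEFAULT_TRACER_ENRICHMENT,
                             glucose_mgdl: float = 0.0,
                             clip_negative: bool = False) -> SourcePartition:
    """Partition blood glucose (mg/dL) by carbon source.

    ``ape_glc`` must come from the glucose C4-C6 fragment (n = 3), the
    triose-phosphate-derived half of the molecule.
    """
    return metabolite_source_partition(ape_glc, ape_pyr, ape_tracer,
                                       glucose_mgdl, clip_negative)


def semiquant_normalize(total_area: float, is_area: float,
                        tissue_mg: float, sample_id: str = "",
                        metabolite: str = "") -> NormalizedAbundance:
    """total signal area / internal-standard area / tissue weight (mg).

    ``total_area`` is the sum of all isotopologue channel areas of the
    metabolite; the internal standard is norleucine.
    """
    if is_area <= 0:
        raise ValueError("internal standard area must be positive")
    if tissue_mg <= 0:
        raise ValueError("tissue weight must be positive")
    if total_area < 0:
        raise ValueError("total area must be non-negative")
    return NormalizedAbundance(total_area / is_area / tissue_mg,
                               sample_id=sample_id, metabolite=metabolite)


# ---------------------------------------------------------------------------
# Tidy-table pipeline layer
# ---------------------------------------------------------------------------

def _mid_from_rows(grp: pd.DataFrame) -> MID:
    grp = grp.sort_values("isotopologue",
                          key=lambda s: s.str.lstrip("M").astype(int))
    frac = grp["fraction"].to_numpy(dtype=float)
    return MID(frac / frac.sum(), len(frac) - 1,
               residual_norm=float(grp["residual_norm"].iloc[0])
               if "residual_norm" in grp else 0.0)


def partition_table(mids: pd.DataFrame, metadata: pd.DataFrame,
                    ape_tracer: float = DEFAULT_TRACER_ENRICHMENT,
                    glucose_metabolite: str = "glucose_C456",
                    pyruvate_metabolite: str = "pyruvate",
                    lactate_metabolite: str = "lactate") -> pd.DataFrame:
    """Per-sample APEs, FCs and glucose/lactate source partitions.

    ``mids``: tidy corrected-MID table (sample_id, metabolite, isotopologue,
    fraction[, residual_norm]).  ``metadata``: one row per sample with
    columns sample_id, genotype, glucose_mgdl, lactate_mM.
    Returns one tidy row per sample.
    """
    meta = metadata.set_index("sample_id")
    rows = []
    for sample, sgrp in mids.groupby("sample_id", sort=True):
        apes = {
            met: ape(_mid_from_rows(g), metabolite=met)
            for met, g in sgrp.groupby("metabolite")
        }
        if pyruvate_metabolite not in apes:
            raise KeyError(f"sample {sample!r}: no {pyruvate_metabolite} MID")
        ape_pyr = apes[pyruvate_metabolite]
        rec = {
            "sample_id": sample,
            "genotype": meta.at[sample, "genotype"],
            "ape_pyruvate": ape_pyr.value,
        }
        if glucose_metabolite in apes:
            part = glucose_source_partition(
                apes[glucose_metabolite], ape_pyr, ape_tracer,
                float(meta.at[sample, "glucose_mgdl"]))
            rec.update({
                "ape_glucose_C456": part.ape_metabolite,
                "glucose_mgdl": part.concentration,
                "glc_fc_from_gavaged": part.fc_from_gavaged,
                "glc_fc_from_blood_pyruvate": part.fc_from_blood_pyruvate,
                "glc_fc_from_non_pyruvate": part.fc_from_non_pyruvate,
                "glc_mgdl_from_gavaged": part.abs_from_gavaged,
                "glc_mgdl_from_endogenous_pyruvate":
                    part.abs_from_endogenous_pyruvate,
                "glc_mgdl_from_non_pyruvate": part.abs_from_non_pyruvate,
                "glc_negative_non_pyruvate": part.negative_non_pyruvate,
            })
        if lactate_metabolite in apes:
            lac = metabolite_source_partition(
                apes[lactate_metabolite], ape_pyr, ape_tracer,
                float(meta.at[sample, "lactate_mM"]))
            rec.update({
                "ape_lactate": lac.ape_metabolite,
                "lactate_mM": lac.concentration,
                "lac_fc_from_gavaged": lac.fc_from_gavaged,
                "lac_fc_from_blood_pyruvate": lac.fc_from_blood_pyruvate,
                "lac_mM_from_gavaged": lac.abs_from_gavaged,
                "lac_mM_from_endogenous_pyruvate":
                    lac.abs_from_endogenous_pyruvate,
                "lac_mM_from_non_pyruvate": lac.abs_from_non_pyruvate,
            })
        rows.append(rec)
    return pd.DataFrame(rows)


def group_summary(partitions: pd.DataFrame,
                  by: str = "genotype") -> pd.DataFrame:
    """Mean +/- SEM of every numeric partition column per group."""
    num = partitions.select_dtypes("number")
    g = partitions[[by]].join(num).groupby(by)
    mean = g.mean().add_suffix("_mean")
    sem = g.sem().add_suffix("_sem")
    return mean.join(sem)
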
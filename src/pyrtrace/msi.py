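"""MALDI-MSI lipid ROI screening.

Pipeline for region-of-interest (ROI) summaries of negative-mode MALDI
imaging data over three kidney zones (cortex, cortex-medulla transition,
medulla) in three genotypes (control, tubular adiponectin knockout "KSPAKO",
tubular adiponectin overexpressor "KSPAPN"):

1. annotate species m/z against a lipid reference table at a ppm tolerance
   (default 5 ppm, [M-H]- masses);
2. drop species with zero or multiple candidate identities (isobaric
   ambiguity cannot be resolved at MALDI-TOF resolution);
3. average intensities over the 9 ROIs per zone x genotype (3 ROIs per
   section, 3 sections);
4. per-species and per-class genotype/control ratio heatmaps (class value =
   ratio of summed intensities within the class);
5. two reciprocal screens on the transition area:
   * up-in-overexpressor: KSPAPN/control > 1, KSPAKO/control < 0.75, and
     mean KSPAPN transition intensity > 100 counts; top 10 by descending
     KSPAPN/control ratio;
   * down-in-overexpressor: KSPAKO/control > 2 and KSPAPN/control < 1;
     top 10 by ascending KSPAPN/control ratio.

Ties in either screen break by ascending m/z.  Intensities are taken as
provided (no cross-section normalisation by default); an optional
per-section median normalisation is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import ElementalFormula, deprotonated_mz, parse_formula

__all__ = [
    "LipidRecord",
    "REGIONS",
    "GENOTYPES",
    "ppm_match",
    "annotate_species",
    "remove_multicandidate",
    "roi_aggregate",
    "genotype_ratio_heatmap",
    "screen_top10_up_in_oe",
    "screen_top10_down_in_oe",
    "median_normalize_sections",
    "load_lipid_db",
]

REGIONS = ("cortex", "transition", "medulla")
GENOTYPES = ("control", "KSPAKO", "KSPAPN")

#: Screen thresholds (transition area): knockout down-regulation bound for
#: the up-screen, knockout up-regulation bound for the down-screen, and the
#: minimum mean overexpressor intensity (instrument counts) guarding against
#: false positives near the noise floor.
KO_DOWN_FOLD = 0.75
KO_UP_FOLD = 2.0
MIN_OE_INTENSITY = 100.0


@dataclass(frozen=True)
class LipidRecord:
    """One reference lipid: name, class label, neutral formula, [M-H]- m/z."""

    name: str
    lipid_class: str
    formula: ElementalFormula
    ref_mz: float

    def __post_init__(self) -> None:
        exact = deprotonated_mz(self.formula)
        if abs(self.ref_mz - exact) / exact * 1e6 > 1.0:
            raise ValueError(
                f"{self.name}: ref m/z {self.ref_mz} deviates from computed "
                f"{exact:.4f} by more than 1 ppm"
            )


def load_lipid_db(path) -> list[LipidRecord]:
    """Read a reference table (TSV: name, lipid_class, formula, ref_mz)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        LipidRecord(r["name"], r["lipid_class"],
                    parse_formula(r["formula"]), float(r["ref_mz"]))
        for _, r in df.iterrows()
    ]


def ppm_match(query_mz: float, db: list[LipidRecord],
              tol_ppm: float = 5.0) -> list[LipidRecord]:
    """All reference records within ``tol_ppm`` of ``query_mz``."""
    if query_mz <= 0:
        raise ValueError("query m/z must be positive")
    if tol_ppm < 0:
        raise ValueError("tolerance must be non-negative")
    return [r for r in db
            if abs(r.ref_mz - query_mz) / query_mz * 1e6 <= tol_ppm]


def annotate_species(mzs, db: list[LipidRecord],
                     tol_ppm: float = 5.0) -> pd.DataFrame:
    """Annotation table: one row per species m/z with its candidate matches."""
    rows = []
    for mz in mzs:
        matches = ppm_match(float(mz), db, tol_ppm)
        rows.append({
            "mz": float(mz),
            "n_candidates": len(matches),
            "candidates": tuple(m.name for m in matches),
            "lipid_class": matches[0].lipid_class if len(matches) == 1 else "",
        })
    return pd.DataFrame(rows)


def remove_multicandidate(annotations: pd.DataFrame) -> pd.DataFrame:
    """Keep only unambiguously annotated species (exactly one candidate).

    Zero-candidate species are dropped too: they carry no class label and
    cannot enter class-level summaries.
    """
    return annotations[annotations["n_candidates"] == 1].reset_index(drop=True)


def median_normalize_sections(roi: pd.DataFrame) -> pd.DataFrame:
    """Scale each section so its median ROI intensity equals the global one."""
    out = roi.copy()
    med = out.groupby("section")["intensity"].transform("median")
    out["intensity"] = out["intensity"] / med * out["intensity"].median()
    return out


def roi_aggregate(roi: pd.DataFrame) -> pd.DataFrame:
    """Mean intensity per species x region x genotype over the ROIs.

    ``roi`` columns: mz, region, genotype, section, roi, intensity.
    Returns columns: mz, region, genotype, mean_intensity, n_roi.  Missing
    ROIs are simply absent from the mean; a region x genotype cell with no
    ROI at all for a species present elsewhere raises.
    """
    if (roi["intensity"] < 0).any():
        raise ValueError("ROI intensities must be non-negative")
    agg = (roi.groupby(["mz", "region", "genotype"], sort=True)["intensity"]
           .agg(mean_intensity="mean", n_roi="count").reset_index())
    cells = agg.groupby("mz").size()
    expected = len(roi["region"].unique()) * len(roi["genotype"].unique())
    short = cells[cells < expected]
    if len(short):
        mz = short.index[0]
        have = set(map(tuple, agg.loc[agg["mz"] == mz,
                                      ["region", "genotype"]].to_numpy()))
        allc = {(r, g) for r in roi["region"].unique()
                for g in roi["genotype"].unique()}
        missing = sorted(allc - have)[0]
        raise ValueError(
            f"species m/z {mz}: no ROI for region={missing[0]!r} "
            f"genotype={missing[1]!r}"
        )
    return agg


def genotype_ratio_heatmap(means: pd.DataFrame,
                           annotations: pd.DataFrame | None = None,
                           control: str = "control",
                           class_mean_of_ratios: bool = False,
                           ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Species x region genotype/control intensity ratios, plus class roll-up.

    Returns ``(species_ratios, class_ratios)``; class ratios require an
    annotation table (single-candidate species only) and are computed as the
    ratio of class-summed intensities (``class_mean_of_ratios=True`` instead
    averages per-species ratios within the class).  Species with a zero
    control mean in any region are excluded and reported via the
    ``excluded_zero_control`` attribute on the species frame.
    """
    wide = means.pivot_table(index=["mz", "region"], columns="genotype",
                             values="mean_intensity")
    geno = [g for g in wide.columns if g != control]
    zero = wide[wide[control] <= 0].reset_index()["mz"].unique()
    wide = wide[wide[control] > 0]
    ratios = wide[geno].div(wide[control], axis=0)
    ratios.columns = [f"{g}/{control}" for g in geno]
    species = ratios.reset_index()
    species.attrs["excluded_zero_control"] = list(zero)

    class_ratios = None
    if annotations is not None:
        ann = remove_multicandidate(annotations)[["mz", "lipid_class"]]
        merged = means.merge(ann, on="mz", how="inner")
        if class_mean_of_ratios:
            sp = species.merge(ann, on="mz", how="inner")
            cols = [c for c in sp.columns if c.endswith(f"/{control}")]
            class_ratios = (sp.groupby(["lipid_class", "region"])[cols]
                            .mean().reset_index())
        else:
            sums = merged.pivot_table(index=["lipid_class", "region"],
                                      columns="genotype",
                                      values="mean_intensity", aggfunc="sum")
            cr = sums[[g for g in geno]].div(sums[control], axis=0)
            cr.columns = [f"{g}/{control}" for g in geno]
            class_ratios = cr.reset_index()
    return species, class_ratios


def _transition_frame(species_ratios: pd.DataFrame, means: pd.DataFrame,
                      annotations: pd.DataFrame | None,
                      oe: str, ko: str, control: str) -> pd.DataFrame:
    tr = species_ratios[species_ratios["region"] == "transition"].copy()
    oe_means = means[(means["region"] == "transition")
                     & (means["genotype"] == oe)][["mz", "mean_intensity"]]
    tr = tr.merge(oe_means, on="mz", how="left")
    if annotations is not None:
        ann = annotations[["mz", "candidates"]]
        tr = tr.merge(ann, on="mz", how="left")
    else:
        tr["candidates"] = [()] * len(tr)
    tr = tr.rename(columns={f"{oe}/{control}": "fold_oe",
                            f"{ko}/{control}": "fold_ko"})
    return tr


def screen_top10_up_in_oe(species_ratios: pd.DataFrame, means: pd.DataFrame,
                          annotations: pd.DataFrame | None = None,
                          oe: str = "KSPAPN", ko: str = "KSPAKO",
                          control: str = "control",
                          min_intensity: float = MIN_OE_INTENSITY,
                          top: int = 10) -> pd.DataFrame:
    """Transition-area species up in the overexpressor but not rescued by
    the knockout: fold_oe > 1, fold_ko < 0.75, mean OE intensity above the
    floor; ranked by descending fold_oe (ties: ascending m/z)."""
    tr = _transition_frame(species_ratios, means, annotations, oe, ko,
                           control)
    hits = tr[(tr["fold_oe"] > 1.0) & (tr["fold_ko"] < KO_DOWN_FOLD)
              & (tr["mean_intensity"] > min_intensity)]
    hits = hits.sort_values(["fold_oe", "mz"], ascending=[False, True])
    cols = ["mz", "candidates", "fold_oe", "fold_ko", "mean_intensity"]
    return hits[cols].head(top).reset_index(drop=True)


def screen_top10_down_in_oe(species_ratios: pd.DataFrame, means: pd.DataFrame,
                            annotations: pd.DataFrame | None = None,
                            oe: str = "KSPAPN", ko: str = "KSPAKO",
                            control: str = "control",
                            top: int = 10) -> pd.DataFrame:
    """Transition-area species most down in the overexpressor among those
    more than 2-fold up in the knockout: fold_ko > 2, fold_oe < 1; ranked
    by ascending fold_oe (ties: ascending m/z)."""
    tr = _transition_frame(species_ratios, means, annotations, oe, ko,
                           control)
    hits = tr[(tr["fold_ko"] > KO_UP_FOLD) & (tr["fold_oe"] < 1.0)]
    hits = hits.sort_values(["fold_oe", "mz"], ascending=[True, True])
    cols = ["mz", "candidates", "fold_oe", "fold_ko", "mean_intensity"]
    return hits[cols].head(top).reset_index(drop=True)
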
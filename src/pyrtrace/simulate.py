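"""Synthetic data with planted ground truth for the tracing and MSI pipelines.

Two generators, both fully determined by a seed:

``simulate_optt``
    Forward model of an oral [U-13C3]pyruvate tolerance test.  Per genotype
    it plants a blood-pyruvate enrichment ``e_pyr`` (M+3 molecule fraction),
    a lactate label-transfer factor ``lambda`` (APE_lactate = lambda *
    APE_pyruvate), a non-pyruvate fraction of glucose carbon ``f_np``, and a
    scrambling fraction ``sigma`` that moves part of the labelled
    glucose-precursor mass from M3 into M1/M2 while preserving the APE
    (mimicking label scrambling through the TCA cycle).  True MIDs are
    convolved through each fragment's natural-abundance correction matrix,
    scaled to a base signal area and multiplied by per-channel lognormal
    noise, yielding raw SIM area tables the analysis pipeline can invert.
    Every generated quantity (true MIDs, APEs, FCs, partitions) is recorded
    in a truth dictionary computed from the generating equations.

``simulate_msi``
    ROI intensity tables for >= 50 lipid species in >= 6 classes across three
    kidney zones and three genotypes, with planted class-level genotype
    fold-changes (species-level multiplicative tweaks give unambiguous screen
    rankings), a matching [M-H]- lipid reference table computed from the
    species formulas, designated duplicate-candidate (isomeric) reference
    entries, designated low-intensity species exercising the intensity floor,
    and <= 2 ppm m/z jitter on the observed species masses.

The model is parameterised directly in the quantities the analysis estimates,
so parameter recovery is an end-to-end check of the analysis equations; it
makes no attempt to model gavage pharmacokinetics or tissue physiology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chem import deprotonated_mz, fragment_library, parse_formula
from .midcorr import build_correction_matrix
from .msi import GENOTYPES, REGIONS, LipidRecord

__all__ = ["GenotypePreset", "SimConfig", "SimOutput", "MSIOutput",
           "simulate_optt", "simulate_msi", "write_outputs"]


@dataclass(frozen=True)
class GenotypePreset:
    """Planted physiology for one genotype."""

    e_pyr: float            # blood pyruvate M+3 enrichment (molecule fraction)
    f_np: float             # fraction of glucose carbon from non-pyruvate sources
    glucose_mgdl: float
    lactate_mM: float


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for both generators.

    Defaults emulate the tracing experiment's structure: a 40 % M+3 gavage
    solution, the overexpressor genotype with a larger non-pyruvate glucose
    share and higher glycaemia than control, multiplicative lognormal signal
    noise, and 8 animals per genotype.
    """

    tracer_enrichment: float = 0.40
    lactate_transfer: float = 0.90      # lambda
    scramble: float = 0.10              # sigma
    noise_cv: float = 0.05
    samples_per_genotype: int = 8
    seed: int = 0
    genotypes: dict[str, GenotypePreset] = field(default_factory=lambda: {
        "control": GenotypePreset(e_pyr=0.20, f_np=0.55,
                                  glucose_mgdl=180.0, lactate_mM=5.0),
        "KSPAPN": GenotypePreset(e_pyr=0.25, f_np=0.70,
                                 glucose_mgdl=230.0, lactate_mM=7.0),
    })
    base_area: float = 1e6
    is_area: float = 1e6                # norleucine internal standard
    concentration_cv: float = 0.05      # per-sample spread of glucose/lactate
    # --- MSI generator ---
    msi_noise_cv: float = 0.10
    msi_mz_jitter_ppm: float = 2.0
    msi_species_per_class: int = 8

    def __post_init__(self) -> None:
        fracs = [self.tracer_enrichment, self.lactate_transfer,
                 self.scramble]
        for g in self.genotypes.values():
            fracs += [g.e_pyr, g.f_np]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.noise_cv < 0 or self.msi_noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.samples_per_genotype < 1:
            raise ValueError("need at least one sample per genotype")
        for name, g in self.genotypes.items():
            if g.e_pyr * (1 + self.scramble) > 1:
                raise ValueError(f"{name}: e_pyr*(1+sigma) exceeds 1")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "genotypes" in raw:
            raw["genotypes"] = {k: GenotypePreset(**v)
                                for k, v in raw["genotypes"].items()}
        return cls(**raw)


@dataclass
class SimOutput:
    areas: pd.DataFrame       # sample_id, metabolite, channel_index, area
    metadata: pd.DataFrame    # sample_id, genotype, glucose_mgdl, lactate_mM,
                              #   tissue_mg, is_area
    truth: dict


@dataclass
class MSIOutput:
    roi: pd.DataFrame         # mz, region, genotype, section, roi, intensity
    db: list[LipidRecord]
    db_table: pd.DataFrame    # name, lipid_class, formula, ref_mz
    truth: dict


# ---------------------------------------------------------------------------
# Tracing generator
# ---------------------------------------------------------------------------

def _m3_mid(e: float) -> np.ndarray:
    return np.array([1.0 - e, 0.0, 0.0, e])


def _scrambled_precursor(e: float, sigma: float) -> np.ndarray:
    """Glucose-precursor MID with APE e and fraction sigma of the labelled
    mass redistributed from M3 into M1/M2, APE-preserving.

    Moving mass sigma*e out of M3 removes 3*sigma*e label units; adding
    sigma*e to each of M1 and M2 restores 1*sigma*e + 2*sigma*e of them,
    with the extra sigma*e of molecule mass taken from M0.
    """
    s = sigma * e
    mid = np.array([1.0 - e - s, s, s, e - s])
    if (mid < 0).any():
        raise ValueError("scramble redistribution drives MID negative")
    return mid


def _ape(mid: np.ndarray) -> float:
    n = len(mid) - 1
    return float((mid * np.arange(n + 1)).sum() / n)


def _lognormal_factors(rng: np.random.Generator, cv: float,
                       size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=size)


def simulate_optt(cfg: SimConfig) -> SimOutput:
    """Generate raw SIM area tables + metadata + an exact truth record."""
    rng = np.random.default_rng(cfg.seed)
    lib = fragment_library()
    frags = {m: lib[m] for m in ("pyruvate", "lactate", "glucose_C456")}
    mats = {m: build_correction_matrix(f) for m, f in frags.items()}

    area_rows, meta_rows = [], []
    truth_samples = {}
    unlabeled = np.array([1.0, 0.0, 0.0, 0.0])
    for genotype in sorted(cfg.genotypes):
        preset = cfg.genotypes[genotype]
        e = preset.e_pyr
        pyr_mid = _m3_mid(e)
        lac_mid = _m3_mid(cfg.lactate_transfer * e)
        precursor = _scrambled_precursor(e, cfg.scramble)
        glc_mid = (1.0 - preset.f_np) * precursor + preset.f_np * unlabeled
        mids = {"pyruvate": pyr_mid, "lactate": lac_mid,
                "glucose_C456": glc_mid}
        apes = {m: _ape(v) for m, v in mids.items()}
        for k in range(cfg.samples_per_genotype):
            sample = f"{genotype}_{k + 1:02d}"
            glucose = preset.glucose_mgdl * float(
                _lognormal_factors(rng, cfg.concentration_cv, 1)[0])
            lactate = preset.lactate_mM * float(
                _lognormal_factors(rng, cfg.concentration_cv, 1)[0])
            tissue_mg = float(rng.uniform(40.0, 60.0))
            for met, mid in mids.items():
                channels = mats[met].matrix @ mid
                noise = _lognormal_factors(rng, cfg.noise_cv, len(channels))
                areas = channels * cfg.base_area * noise
                for ci, a in enumerate(areas):
                    area_rows.append((sample, met, ci, a))
            meta_rows.append((sample, genotype, glucose, lactate,
                              tissue_mg, cfg.is_area))
            fc_bp = apes["glucose_C456"] / apes["pyruvate"]
            fc_gav = apes["glucose_C456"] / cfg.tracer_enrichment
            truth_samples[sample] = {
                "genotype": genotype,
                "mids": {m: list(v) for m, v in mids.items()},
                "apes": apes,
                "fc_lactate_from_pyruvate":
                    apes["lactate"] / apes["pyruvate"],
                "fc_glc_from_blood_pyruvate": fc_bp,
                "fc_glc_from_gavaged": fc_gav,
                "fc_glc_from_non_pyruvate": 1.0 - fc_bp,
                "glucose_mgdl": glucose,
                "lactate_mM": lactate,
                "glc_mgdl_from_gavaged": fc_gav * glucose,
                "glc_mgdl_from_endogenous_pyruvate":
                    (fc_bp - fc_gav) * glucose,
                "glc_mgdl_from_non_pyruvate": (1.0 - fc_bp) * glucose,
            }
    areas = pd.DataFrame(area_rows, columns=["sample_id", "metabolite",
                                             "channel_index", "area"])
    metadata = pd.DataFrame(meta_rows, columns=[
        "sample_id", "genotype", "glucose_mgdl", "lactate_mM", "tissue_mg",
        "is_area"])
    truth = {
        "config": {
            "tracer_enrichment": cfg.tracer_enrichment,
            "lactate_transfer": cfg.lactate_transfer,
            "scramble": cfg.scramble,
            "noise_cv": cfg.noise_cv,
            "seed": cfg.seed,
            "genotypes": {k: asdict(v) for k, v in cfg.genotypes.items()},
        },
        "samples": truth_samples,
    }
    return SimOutput(areas=areas, metadata=metadata, truth=truth)


# ---------------------------------------------------------------------------
# MSI generator
# ---------------------------------------------------------------------------

# neutral-formula builders per lipid class, parameterised by total acyl/chain
# carbons c and double bonds d
_CLASS_FORMULA = {
    "PS": lambda c, d: f"C{c + 6}H{2 * c - 2 * d + 10}NO10P",
    "PE": lambda c, d: f"C{c + 5}H{2 * c - 2 * d + 10}NO8P",
    "PI": lambda c, d: f"C{c + 9}H{2 * c - 2 * d + 15}O13P",
    "PG": lambda c, d: f"C{c + 6}H{2 * c - 2 * d + 11}O10P",
    "SM": lambda c, d: f"C{c + 5}H{2 * c - 2 * d + 13}N2O6P",
    "Cer": lambda c, d: f"C{c}H{2 * c - 2 * d + 1}NO3",
    "SHexCer": lambda c, d: f"C{c + 6}H{2 * c - 2 * d + 11}NO11S",
    "DG": lambda c, d: f"C{c + 3}H{2 * c - 2 * d + 4}O5",
    "FA": lambda c, d: f"C{c}H{2 * c - 2 * d}O2",
}

# planted class-level genotype multipliers in the transition area
# (KSPAKO/control, KSPAPN/control); cortex/medulla get the square root of
# the effect (changes concentrate in the transition zone)
_CLASS_EFFECT = {
    "PS": (0.60, 1.80),        # up in OE, down in KO  -> up-screen pool
    "FA": (0.60, 1.80),
    "SHexCer": (2.50, 0.70),   # up in KO, down in OE  -> down-screen pool
    "SM": (2.50, 0.70),
    "Cer": (2.50, 0.70),
    "DG": (2.50, 0.70),
    "PE": (1.00, 1.00),        # neutral
    "PI": (1.00, 0.95),
    "PG": (1.00, 1.05),
}

_REGION_FACTOR = {"cortex": 1.0, "transition": 1.2, "medulla": 0.8}


def _msi_species(cfg: SimConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic species panel: class, chain, formula, exact m/z,
    base intensity and per-species genotype multipliers."""
    rows = []
    for cls in sorted(_CLASS_FORMULA):
        build = _CLASS_FORMULA[cls]
        for k in range(cfg.msi_species_per_class):
            if cls == "FA":
                c, d = 16 + 2 * (k // 2), k % 2
            else:
                c, d = 32 + 2 * (k // 2), k % 2 + (1 if cls in
                                                   ("SM", "Cer", "SHexCer")
                                                   else 0)
            formula = build(c, d)
            mz = deprotonated_mz(parse_formula(formula))
            ko_base, oe_base = _CLASS_EFFECT[cls]
            # species-level tweaks keep every species inside its class's
            # screen-qualification band while making rankings unambiguous
            ko = ko_base * float(rng.uniform(0.85, 1.15))
            oe = oe_base * float(rng.uniform(0.85, 1.15))
            base = float(rng.uniform(200.0, 2000.0))
            rows.append({"name": f"{cls} {c}:{d}", "lipid_class": cls,
                         "chain": f"{c}:{d}", "formula": formula,
                         "exact_mz": mz, "base_intensity": base,
                         "ko_mult": ko, "oe_mult": oe})
    df = pd.DataFrame(rows)
    # two designated low-abundance up-screen-band species exercise the
    # intensity floor of the up-screen
    low = df.index[df["lipid_class"] == "PS"][:2]
    df.loc[low, "base_intensity"] = 30.0
    return df


def simulate_msi(cfg: SimConfig) -> MSIOutput:
    """Generate an ROI intensity table, a lipid reference table and truth."""
    rng = np.random.default_rng(cfg.seed + 1)
    species = _msi_species(cfg, rng)

    # observed species m/z: exact [M-H]- with <= jitter ppm mass error
    jitter = rng.uniform(-cfg.msi_mz_jitter_ppm, cfg.msi_mz_jitter_ppm,
                         len(species))
    species["obs_mz"] = species["exact_mz"] * (1.0 + jitter * 1e-6)

    db: list[LipidRecord] = []
    db_rows = []
    for _, r in species.iterrows():
        rec = LipidRecord(r["name"], r["lipid_class"],
                          parse_formula(r["formula"]), float(r["exact_mz"]))
        db.append(rec)
        db_rows.append((rec.name, rec.lipid_class, r["formula"], rec.ref_mz))
    # duplicate-candidate entries: isomeric species (same elemental formula,
    # different chain combination) for four neutral-class species
    dup_idx = species.index[species["lipid_class"] == "PE"][:4]
    for i in dup_idx:
        r = species.loc[i]
        c, d = map(int, r["chain"].split(":"))
        alt = f"{r['lipid_class']} {c - 16}:{d}/16:0"  # chain-isomer label
        rec = LipidRecord(alt, r["lipid_class"],
                          parse_formula(r["formula"]), float(r["exact_mz"]))
        db.append(rec)
        db_rows.append((rec.name, rec.lipid_class, r["formula"], rec.ref_mz))
    db_table = pd.DataFrame(db_rows, columns=["name", "lipid_class",
                                              "formula", "ref_mz"])

    # planted noise-free means and the ROI draws around them
    roi_rows = []
    mean_rows = []
    for _, r in species.iterrows():
        for region in REGIONS:
            rf = _REGION_FACTOR[region]
            for genotype in GENOTYPES:
                if genotype == "control":
                    mult = 1.0
                else:
                    m = r["ko_mult"] if genotype == "KSPAKO" else r["oe_mult"]
                    mult = m if region == "transition" else float(np.sqrt(m))
                mean = r["base_intensity"] * rf * mult
                mean_rows.append((float(r["obs_mz"]), r["name"],
                                  r["lipid_class"], region, genotype, mean))
                noise = _lognormal_factors(rng, cfg.msi_noise_cv, 9)
                for section in range(1, 4):
                    for roi in range(1, 4):
                        val = mean * noise[(section - 1) * 3 + (roi - 1)]
                        roi_rows.append((float(r["obs_mz"]), region, genotype,
                                         section, roi, val))
    roi = pd.DataFrame(roi_rows, columns=["mz", "region", "genotype",
                                          "section", "roi", "intensity"])
    means = pd.DataFrame(mean_rows, columns=[
        "mz", "name", "lipid_class", "region", "genotype", "mean"])

    truth = _msi_truth(species, means, dup_idx)
    return MSIOutput(roi=roi, db=db, db_table=db_table, truth=truth)


def _msi_truth(species: pd.DataFrame, means: pd.DataFrame,
               dup_idx) -> dict:
    tr = species.copy()
    oe_mean = means[(means["region"] == "transition")
                    & (means["genotype"] == "KSPAPN")]
    tr = tr.merge(oe_mean[["name", "mean"]].rename(
        columns={"mean": "oe_transition_mean"}), on="name")
    up = tr[(tr["oe_mult"] > 1.0) & (tr["ko_mult"] < 0.75)
            & (tr["oe_transition_mean"] > 100.0)]
    up = up.sort_values(["oe_mult", "obs_mz"], ascending=[False, True])
    down = tr[(tr["ko_mult"] > 2.0) & (tr["oe_mult"] < 1.0)]
    down = down.sort_values(["oe_mult", "obs_mz"], ascending=[True, True])

    single = species.drop(index=dup_idx)
    class_ratio = {}
    for region in REGIONS:
        sub = means[means["region"] == region]
        sub = sub[sub["name"].isin(single["name"])]
        piv = sub.pivot_table(index="lipid_class", columns="genotype",
                              values="mean", aggfunc="sum")
        class_ratio[region] = {
            cls: {"KSPAKO/control": piv.at[cls, "KSPAKO"]
                  / piv.at[cls, "control"],
                  "KSPAPN/control": piv.at[cls, "KSPAPN"]
                  / piv.at[cls, "control"]}
            for cls in piv.index
        }
    return {
        "species": species.drop(columns=["base_intensity"]).to_dict("records"),
        "planted_means": means.to_dict("records"),
        "duplicate_candidate_mzs": [float(species.at[i, "obs_mz"])
                                    for i in dup_idx],
        "up_screen_mzs": [float(v) for v in up["obs_mz"].head(10)],
        "down_screen_mzs": [float(v) for v in down["obs_mz"].head(10)],
        "n_up_qualifying": int(len(up)),
        "n_down_qualifying": int(len(down)),
        "class_transition_ratios": class_ratio["transition"],
        "class_ratios": class_ratio,
    }


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------

def write_outputs(out_dir, sim: SimOutput | None = None,
                  msi: MSIOutput | None = None) -> None:
    """Write generator outputs as TSVs plus a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict = {}
    if sim is not None:
        sim.areas.to_csv(out / "sim_areas.tsv", sep="\t", index=False)
        sim.metadata.to_csv(out / "sample_metadata.tsv", sep="\t",
                            index=False)
        truth["optt"] = sim.truth
    if msi is not None:
        msi.roi.to_csv(out / "msi_roi.tsv", sep="\t", index=False)
        msi.db_table.to_csv(out / "lipid_db.tsv", sep="\t", index=False)
        truth["msi"] = msi.truth
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
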
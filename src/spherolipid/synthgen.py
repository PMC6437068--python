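"""Synthetic two-group lipidomics datasets with full ground truth.

The generator emulates the statistical structure of a spheroid-vs-adherent
(EMT) breast-cancer lipidomics experiment: n = 5 samples per group
("Adherent", "Sphere"), 123 lipid species over eight classes with
class-specific spiked internal standards and log-normal intensities, MS/MS
spectra with hard decoys for the identification benchmark, GC-MS FAME peak
areas, and transcript log2 fold-changes for the pathway overlay.

Planted EMT effects (the "paper-faithful" preset): ceramides up, ether
phospholipids (PC O-, PE O-) down, species carrying a 16:1 chain up,
species carrying a >=3-double-bond chain down; in the fatty-acid profile
the MUFA/SFA desaturation indices rise while the elongation and DHA
indices fall; SCD/ACOX3/FADS1 transcripts rise while
PTPLB/PECR/ELOVL2/ELOVL3 fall.  All outputs are reproducible per seed and
every planted quantity is returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .identify import FragmentationRule, SpectrumRecord, load_fragmentation_rules
from .nomenclature import (
    LipidSpecies,
    adduct_polarity,
    default_adducts,
    parse_lipid_name,
    species_mz,
)
from .pathway import ExpressionOverlay
from .quantify import PeakTable, default_internal_standards

__all__ = [
    "GeneratorConfig",
    "LipidomeTruth",
    "MsmsTruth",
    "FameTruth",
    "ExpressionTruth",
    "default_species_library",
    "generate_lipidome",
    "generate_msms",
    "generate_fame",
    "generate_expression",
    "fame_response_factors",
    "expected_index_directions",
    "FAME_INTERNAL_STANDARD",
]


# ---------------------------------------------------------------------------
# species library: 123 species over 8 classes, unique (class, C:DB)
# ---------------------------------------------------------------------------

_LPC = ["14:0", "16:0", "16:1", "18:0", "18:1", "18:2", "20:4n6", "22:6n3"]

_PC_PAIRS = [
    "14:0/14:0", "14:0/16:0", "14:0/16:1", "16:0/16:0", "16:0/16:1",
    "16:1/16:1", "16:0/18:0", "16:0/18:1", "16:1/18:1", "16:1/18:2",
    "14:0/20:4n6", "18:0/18:0", "18:0/18:1", "18:1/18:1", "18:1/18:2",
    "16:0/20:4n6", "16:1/20:4n6", "14:0/22:6n3", "18:0/20:3n6",
    "18:0/20:4n6", "18:1/20:4n6", "16:0/22:6n3", "16:1/22:6n3",
    "18:0/22:5n3", "18:0/22:6n3", "18:1/22:6n3", "18:2/22:6n3",
    "20:3n6/22:6n3", "20:4n6/22:6n3", "22:6n3/22:6n3",
]

_PC_O = [
    "O-16:0/16:0", "O-16:0/16:1", "O-16:0/18:1", "O-16:0/18:2",
    "O-16:0/20:4n6", "O-16:0/22:6n3", "O-18:0/18:1", "O-18:1/18:1",
    "O-18:1/20:4n6", "O-18:1/22:6n3",
]

_PE_PAIRS = [
    "14:0/16:0", "16:0/16:0", "16:0/16:1", "16:0/18:1", "16:1/18:1",
    "16:1/18:2", "18:0/18:0", "18:0/18:1", "18:1/18:1", "18:1/18:2",
    "16:0/20:4n6", "16:1/20:4n6", "18:0/20:3n6", "18:0/20:4n6",
    "18:1/20:4n6", "16:0/22:6n3", "16:1/22:6n3", "18:0/22:5n3",
    "18:0/22:6n3", "18:1/22:6n3",
]

_PE_O = [
    "O-16:0/16:1", "O-16:0/18:1", "O-16:0/18:2", "O-16:0/20:4n6",
    "O-16:0/22:6n3", "O-18:0/18:1", "O-18:1/18:1", "O-18:1/20:4n6",
    "O-18:0/22:5n3", "O-18:1/22:6n3",
]

_TG_TRIPLES = [
    "14:0/16:0/16:0", "14:0/16:0/16:1", "16:0/16:0/16:0", "16:0/16:0/16:1",
    "16:0/16:1/16:1", "16:1/16:1/16:1", "16:0/16:0/18:0", "16:0/16:0/18:1",
    "16:0/16:1/18:1", "16:1/16:1/18:1", "16:0/18:0/18:1", "16:0/18:1/18:1",
    "16:1/18:1/18:1", "16:1/18:1/18:2", "16:1/18:2/18:2", "18:0/18:0/18:1",
    "18:0/18:1/18:1", "18:1/18:1/18:1", "18:1/18:1/18:2", "18:1/18:2/18:2",
    "18:2/18:2/18:2", "16:0/18:1/22:6n3", "16:1/18:1/22:6n3",
    "18:2/18:2/22:6n3", "16:0/22:6n3/22:6n3",
]

_SM_ACYLS = ["14:0", "16:0", "16:1", "18:0", "18:1", "20:0", "20:1", "22:0",
             "22:1", "24:0", "24:1", "26:0"]

_CER_ACYLS = ["14:0", "16:0", "18:0", "18:1", "20:0", "22:0", "24:0", "24:1"]


def default_species_library() -> list[LipidSpecies]:
    """The simulated MCF-7 lipidome: 123 molecular species, one per
    (class, total C:DB) pair so masses are unambiguous within a class."""
    names: list[str] = []
    names += [f"LPC({a})" for a in _LPC]
    names += [f"PC({p})" for p in _PC_PAIRS]
    names += [f"PC({p})" for p in _PC_O]
    names += [f"PE({p})" for p in _PE_PAIRS]
    names += [f"PE({p})" for p in _PE_O]
    names += [f"TG({p})" for p in _TG_TRIPLES]
    names += [f"SM(d18:1/{a})" for a in _SM_ACYLS]
    names += [f"Cer(d18:1/{a})" for a in _CER_ACYLS]
    return [parse_lipid_name(n) for n in names]


# class-level log10 location of baseline amounts (ng), reflecting the
# relative abundance of the classes in cultured cells
_CLASS_LOG10_MEAN = {
    "LPC": 1.3, "PC": 2.5, "PC O-": 1.8, "PE": 2.2, "PE O-": 1.8,
    "TG": 2.7, "SM": 2.0, "Cer": 1.4,
}

_GROUPS = ("Adherent", "Sphere")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic experiment.

    Effects are multiplicative shifts applied to Sphere-group means; the
    defaults define the paper-faithful preset.  ``null()`` switches every
    effect off for type-I-error simulations.
    """

    n_per_group: int = 5
    # log-normal intensity model (log10 units)
    species_spread_log10: float = 0.5
    noise_sd_log10: float = 0.25
    response_sd_log10: float = 0.20
    standard_noise_sd_log10: float = 0.05
    protein_mean_ug: float = 100.0
    protein_sd_ug: float = 10.0
    # planted multiplicative effects on Sphere means, sized so that with
    # n = 5 per group and 0.25 log10-unit noise roughly 60% of species
    # clear the P<0.05 / FDR<0.10 gates after closure + preprocessing
    effect_cer: float = 6.0
    effect_ether: float = 0.15
    effect_c16_1: float = 5.0
    effect_pufa: float = 0.18
    # MS/MS benchmark
    mass_error_ppm: float = 2.0  # uniform half-width (instrument accuracy bound)
    fragment_jitter_da: float = 0.004
    decoy_fraction: float = 0.20
    n_noise_peaks: int = 3
    # GC-MS FAME
    fame_total_ug: float = 50.0
    fame_is_amount_ug: float = 5.0
    fame_area_noise_sd_log10: float = 0.035
    fame_scale_sd_log10: float = 0.15
    # transcript overlay
    expression_noise_sd: float = 0.10

    @classmethod
    def null(cls) -> "GeneratorConfig":
        """No planted effects anywhere (for type-I error simulations)."""
        return cls(effect_cer=1.0, effect_ether=1.0, effect_c16_1=1.0, effect_pufa=1.0)


# ---------------------------------------------------------------------------
# lipidome peak table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidomeTruth:
    """Planted species effects and the noiseless group means (ng)."""

    species_effect: Mapping[str, float]  # Sphere/Adherent fold change
    mean_amount: pd.DataFrame  # species x group, ng
    class_direction: Mapping[str, str]  # planted class-level direction


def _species_effect(species: LipidSpecies, config: GeneratorConfig) -> float:
    effect = 1.0
    if species.lipid_class == "Cer":
        effect *= config.effect_cer
    if species.lipid_class in ("PC O-", "PE O-"):
        effect *= config.effect_ether
    chains = species.acyls
    if any(a.carbons == 16 and a.double_bonds == 1 for a in chains):
        effect *= config.effect_c16_1
    if any(a.double_bonds >= 3 for a in chains):
        effect *= config.effect_pufa
    return effect


def generate_lipidome(
    config: GeneratorConfig, seed: int
) -> tuple[PeakTable, LipidomeTruth]:
    """Two-group LC-MS peak table with spiked class standards.

    Intensities are log-normal around species baselines drawn per class;
    every sample carries a global instrument response factor (removed by
    internal-standard normalization) and the five spiked standards at
    their nominal amounts with small pipetting noise.
    """
    rng = np.random.default_rng(seed)
    library = default_species_library()
    if config.n_per_group < 2:
        raise ValueError("need >=2 samples per group")

    samples = [f"A{i+1}" for i in range(config.n_per_group)] + [
        f"S{i+1}" for i in range(config.n_per_group)
    ]
    groups = ["Adherent"] * config.n_per_group + ["Sphere"] * config.n_per_group

    baseline = {
        s.name: 10.0
        ** (
            _CLASS_LOG10_MEAN[s.lipid_class]
            + config.species_spread_log10 * rng.standard_normal()
        )
        for s in library
    }
    effects = {s.name: _species_effect(s, config) for s in library}
    mean_amount = pd.DataFrame(
        {
            "Adherent": pd.Series(baseline),
            "Sphere": pd.Series({k: baseline[k] * effects[k] for k in baseline}),
        }
    )

    response = 10.0 ** (config.response_sd_log10 * rng.standard_normal(len(samples)))

    is_map = default_internal_standards()
    standard_specs = sorted({v for v in is_map.standards.values()})

    feature_rows = []
    intensity_rows = []
    for s in library:
        amounts = np.array(
            [mean_amount.loc[s.name, g] for g in groups], dtype=float
        )
        noise = 10.0 ** (config.noise_sd_log10 * rng.standard_normal(len(samples)))
        intensity_rows.append(amounts * noise * response)
        adduct = default_adducts(s.lipid_class)[0]
        feature_rows.append(
            {
                "species": s.name,
                "lipid_class": s.lipid_class,
                "mz": species_mz(s, adduct),
                "adduct": adduct,
                "is_standard": False,
            }
        )
    for std_name, spiked_ng in standard_specs:
        std = parse_lipid_name(std_name)
        noise = 10.0 ** (
            config.standard_noise_sd_log10 * rng.standard_normal(len(samples))
        )
        intensity_rows.append(np.full(len(samples), spiked_ng) * noise * response)
        adduct = default_adducts(std.lipid_class)[0]
        feature_rows.append(
            {
                "species": std.name,
                "lipid_class": std.lipid_class,
                "mz": species_mz(std, adduct),
                "adduct": adduct,
                "is_standard": True,
            }
        )

    features = pd.DataFrame(feature_rows)
    features.index = pd.Index(features["species"], name="feature")
    intensities = pd.DataFrame(
        np.vstack(intensity_rows), index=features.index, columns=samples
    )
    protein = np.maximum(
        config.protein_mean_ug + config.protein_sd_ug * rng.standard_normal(len(samples)),
        1.0,
    )
    sample_meta = pd.DataFrame(
        {"group": groups, "protein_ug": protein}, index=pd.Index(samples, name="sample")
    )

    class_direction = {}
    if config.effect_cer != 1.0:
        class_direction["Cer"] = "up" if config.effect_cer > 1 else "down"
    if config.effect_ether != 1.0:
        direction = "up" if config.effect_ether > 1 else "down"
        class_direction["PC O-"] = direction
        class_direction["PE O-"] = direction

    table = PeakTable(intensities=intensities, features=features, samples=sample_meta)
    truth = LipidomeTruth(
        species_effect=effects, mean_amount=mean_amount, class_direction=class_direction
    )
    return table, truth


# ---------------------------------------------------------------------------
# MS/MS benchmark spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MsmsTruth:
    """Per-spectrum ground truth: the species name, or None for decoys."""

    labels: tuple[Optional[str], ...]


# decoy donors: swap in the class-diagnostic fragments of a different rule
# family with the same polarity (hard negatives for the rule engine)
_DECOY_DONOR = {
    "LPC": "PE", "PC": "PE", "PC O-": "PE", "SM": "Cer",
    "PE": "PC", "PE O-": "PC", "Cer": "PC",
    "TG": None,  # positive mode: replace NH3 loss by the forbidden headgroup ion
}


def _realize_fragments(
    rule: FragmentationRule,
    precursor_mz: float,
    rng: np.random.Generator,
    jitter: float,
) -> list[tuple[float, float]]:
    peaks = []
    for spec in rule.required:
        mz = spec.target_mz(precursor_mz) + rng.uniform(-jitter, jitter)
        peaks.append((mz, 10.0 ** rng.uniform(3, 5)))
    return peaks


def _noise_peaks(
    rng: np.random.Generator,
    n: int,
    precursor_mz: float,
    avoid: Sequence[float],
    min_distance: float = 0.05,
) -> list[tuple[float, float]]:
    peaks = []
    while len(peaks) < n:
        mz = rng.uniform(100.0, max(150.0, precursor_mz - 20.0))
        if all(abs(mz - a) > min_distance for a in avoid):
            peaks.append((mz, 10.0 ** rng.uniform(1, 3)))
    return peaks


def generate_msms(
    species_list: Sequence[LipidSpecies] | None = None,
    rules: Mapping[tuple[str, str], FragmentationRule] | None = None,
    mass_error_ppm: float = 2.0,
    decoy_fraction: float = 0.20,
    seed: int = 0,
    n_noise_peaks: int = 3,
    fragment_jitter_da: float = 0.004,
) -> tuple[list[SpectrumRecord], MsmsTruth]:
    """MS/MS spectra for a species list plus hard decoys.

    True spectra carry the class-required fragments (with small m/z
    jitter) and random noise peaks; precursor errors are uniform within
    +/- ``mass_error_ppm`` (a calibrated-instrument accuracy bound).
    Decoys sit exactly on a real precursor m/z but carry the diagnostic
    fragments of a different class family, so they must be rejected by the
    rules, not by mass.  ``decoy_fraction`` is relative to the number of
    true spectra.
    """
    rng = np.random.default_rng(seed)
    if species_list is None:
        species_list = default_species_library()
    if rules is None:
        rules = load_fragmentation_rules()

    spectra: list[SpectrumRecord] = []
    labels: list[Optional[str]] = []

    all_diagnostics: dict[str, list[float]] = {}
    for (cls, pol), rule in rules.items():
        targets = [
            spec.target_mz(0.0) for spec in (*rule.required, *rule.forbidden)
            if spec.kind in ("ion", "mz")
        ]
        all_diagnostics.setdefault(pol, []).extend(targets)

    for i, species in enumerate(species_list):
        adduct = default_adducts(species.lipid_class)[0]
        polarity = adduct_polarity(adduct)
        rule = rules.get((species.lipid_class, polarity))
        if rule is None:
            raise KeyError(
                f"no fragmentation rule for {species.lipid_class!r} polarity {polarity!r}"
            )
        theo = species_mz(species, adduct)
        precursor = theo * (1.0 + rng.uniform(-mass_error_ppm, mass_error_ppm) * 1e-6)
        peaks = _realize_fragments(rule, precursor, rng, fragment_jitter_da)
        avoid = list(all_diagnostics.get(polarity, [])) + [
            precursor - loss
            for loss in (17.0265, 18.0106, 30.0106, 60.0211)
        ]
        peaks += _noise_peaks(rng, n_noise_peaks, precursor, avoid)
        spectra.append(
            SpectrumRecord(
                precursor_mz=precursor,
                polarity=polarity,
                peaks=tuple(sorted(peaks)),
                retention_time=float(rng.uniform(1.0, 20.0)),
                title=f"true_{i}_{species.name}",
            )
        )
        labels.append(species.name)

    n_decoys = int(round(decoy_fraction * len(species_list)))
    decoy_bases = rng.choice(len(species_list), size=n_decoys, replace=True)
    for j, base_idx in enumerate(decoy_bases):
        base = species_list[int(base_idx)]
        adduct = default_adducts(base.lipid_class)[0]
        polarity = adduct_polarity(adduct)
        theo = species_mz(base, adduct)
        precursor = theo * (1.0 + rng.uniform(-mass_error_ppm, mass_error_ppm) * 1e-6)
        donor_cls = _DECOY_DONOR[base.lipid_class]
        if donor_cls is not None:
            donor_rule = rules[(donor_cls, polarity)]
            peaks = _realize_fragments(donor_rule, precursor, rng, fragment_jitter_da)
        else:
            # TG decoy: the forbidden phosphocholine headgroup ion instead of
            # the ammonia loss
            base_rule = rules[(base.lipid_class, polarity)]
            peaks = [
                (spec.target_mz(precursor) + rng.uniform(-fragment_jitter_da, fragment_jitter_da),
                 10.0 ** rng.uniform(3, 5))
                for spec in base_rule.forbidden
            ]
        avoid = list(all_diagnostics.get(polarity, [])) + [
            precursor - loss
            for loss in (17.0265, 18.0106, 30.0106, 60.0211)
        ]
        peaks += _noise_peaks(rng, n_noise_peaks, precursor, avoid)
        spectra.append(
            SpectrumRecord(
                precursor_mz=precursor,
                polarity=polarity,
                peaks=tuple(sorted(peaks)),
                retention_time=float(rng.uniform(1.0, 20.0)),
                title=f"decoy_{j}_{base.name}",
            )
        )
        labels.append(None)

    return spectra, MsmsTruth(labels=tuple(labels))


# ---------------------------------------------------------------------------
# GC-MS FAME areas
# ---------------------------------------------------------------------------

# adherent-state esterified fatty-acid composition (%) of cultured breast
# cancer cells, and the Sphere-state multiplicative shifts that produce
# rising desaturation indices and falling elongation / DHA indices
_FAME_BASELINE = {
    "14:0": 2.0, "16:0": 28.0, "16:1": 5.0, "18:0": 15.0, "18:1": 25.0,
    "18:2n6": 6.0, "20:0": 1.0, "20:3n6": 1.5, "20:4n6": 6.0, "22:0": 0.8,
    "22:5n3": 1.2, "22:6n3": 2.5, "24:0": 0.6,
}

_FAME_SPHERE_SHIFT = {
    "16:0": 1.30, "16:1": 2.60, "18:0": 0.70, "18:1": 1.40,
    "20:0": 0.45, "22:0": 0.25, "20:3n6": 0.50, "20:4n6": 0.70,
    "22:5n3": 0.90, "22:6n3": 0.35,
}

# relative response factors of the FAME standards (near unity by design)
_FAME_RRF = {
    "14:0": 0.97, "16:0": 1.00, "16:1": 0.99, "18:0": 1.02, "18:1": 1.01,
    "18:2n6": 0.98, "20:0": 1.04, "20:3n6": 0.97, "20:4n6": 0.95,
    "22:0": 1.05, "22:5n3": 0.94, "22:6n3": 0.93, "24:0": 1.06,
}

FAME_INTERNAL_STANDARD = "23:0"


@dataclass(frozen=True)
class FameTruth:
    """Noiseless group compositions, shifts and expected index directions."""

    composition: pd.DataFrame  # fatty acid x group, percent
    shift: Mapping[str, float]
    rrf: Mapping[str, float]
    index_direction: Mapping[str, str]  # step label -> up/down


def expected_index_directions(shift: Mapping[str, float]) -> dict[str, str]:
    """Directions implied by the Sphere shifts for the packaged steps."""
    pairs = [
        ("16:1", "16:0"), ("18:1", "18:0"), ("18:0", "16:0"),
        ("20:0", "18:0"), ("22:0", "20:0"), ("20:4n6", "20:3n6"),
        ("22:6n3", "22:5n3"),
    ]
    out = {}
    for product, substrate in pairs:
        ratio = shift.get(product, 1.0) / shift.get(substrate, 1.0)
        if ratio == 1.0:
            continue
        out[f"{product}/{substrate}"] = "up" if ratio > 1 else "down"
    return out


def generate_fame(
    config: GeneratorConfig, seed: int
) -> tuple[pd.DataFrame, FameTruth]:
    """GC-MS FAME peak-area table (fatty acids + C23:0 standard x samples).

    areas = true amount x rrf x per-sample detector scale x log-normal
    noise; the C23:0 internal standard is spiked at a constant amount.
    Under the null preset the Sphere shifts are switched off.
    """
    rng = np.random.default_rng(seed)
    null = (
        config.effect_cer == 1.0
        and config.effect_ether == 1.0
        and config.effect_c16_1 == 1.0
        and config.effect_pufa == 1.0
    )
    shift = {} if null else dict(_FAME_SPHERE_SHIFT)

    base = pd.Series(_FAME_BASELINE, dtype=float)
    adherent = base / base.sum() * 100.0
    sphere_raw = base * pd.Series({fa: shift.get(fa, 1.0) for fa in base.index})
    sphere = sphere_raw / sphere_raw.sum() * 100.0
    composition = pd.DataFrame({"Adherent": adherent, "Sphere": sphere})

    samples = [f"A{i+1}" for i in range(config.n_per_group)] + [
        f"S{i+1}" for i in range(config.n_per_group)
    ]
    groups = ["Adherent"] * config.n_per_group + ["Sphere"] * config.n_per_group

    areas = {}
    for sample, group in zip(samples, groups):
        scale = 10.0 ** (config.fame_scale_sd_log10 * rng.standard_normal())
        amounts = composition[group] / 100.0 * config.fame_total_ug * scale
        noise = 10.0 ** (
            config.fame_area_noise_sd_log10 * rng.standard_normal(len(amounts))
        )
        col = amounts * pd.Series(_FAME_RRF).reindex(amounts.index) * noise
        is_noise = 10.0 ** (config.fame_area_noise_sd_log10 * rng.standard_normal())
        col.loc[FAME_INTERNAL_STANDARD] = config.fame_is_amount_ug * is_noise
        areas[sample] = col
    table = pd.DataFrame(areas)
    table.index.name = "fatty_acid"

    truth = FameTruth(
        composition=composition,
        shift=shift,
        rrf=dict(_FAME_RRF),
        index_direction=expected_index_directions(shift),
    )
    return table, truth


def fame_response_factors() -> dict[str, float]:
    """The generator's relative response factors (for the analysis side)."""
    return dict(_FAME_RRF)


# ---------------------------------------------------------------------------
# transcript fold-changes
# ---------------------------------------------------------------------------

_EXPRESSION_MEANS = {
    "SCD": 1.5, "ACOX3": 0.8, "FADS1": 0.7,
    "PTPLB": -1.2, "PECR": -1.0, "ELOVL2": -2.0, "ELOVL3": -1.5,
}


@dataclass(frozen=True)
class ExpressionTruth:
    mean_log2fc: Mapping[str, float]


def generate_expression(
    config: GeneratorConfig, seed: int
) -> tuple[ExpressionOverlay, ExpressionTruth]:
    """Sphere-vs-Adherent transcript log2 fold-changes for the fatty-acid
    regulators, drawn around the preset means with measurement noise."""
    rng = np.random.default_rng(seed)
    values = {
        gene: mean + config.expression_noise_sd * rng.standard_normal()
        for gene, mean in _EXPRESSION_MEANS.items()
    }
    overlay = ExpressionOverlay(log2fc=values, source="synthetic")
    return overlay, ExpressionTruth(mean_log2fc=dict(_EXPRESSION_MEANS))
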
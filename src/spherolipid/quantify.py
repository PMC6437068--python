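"""Intensity-to-amount conversion and composition analysis.

Identified LC-MS peak intensities become ng-equivalent amounts via
class-specific spiked internal standards, then amounts per microgram of
protein; compositions close to 100% at class or species grain.  The GC-MS
path converts FAME peak areas to relative fatty-acid compositions via
per-fatty-acid relative response factors, and the lipidome itself can be
decomposed into an esterified fatty-acid profile by crediting each
molecular species' amount once per chain occurrence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .nomenclature import parse_lipid_name

logger = logging.getLogger(__name__)

__all__ = [
    "PeakTable",
    "InternalStandardMap",
    "FattyAcidProfile",
    "MissingStandard",
    "InvalidProtein",
    "DegenerateSample",
    "default_internal_standards",
    "is_normalize",
    "protein_normalize",
    "class_composition",
    "species_composition",
    "fame_composition",
    "lipidome_to_fa_profile",
    "tidy_amounts",
]


class MissingStandard(ValueError):
    """Internal standard absent, or zero intensity in some sample."""


class InvalidProtein(ValueError):
    """Non-positive protein amount."""


class DegenerateSample(ValueError):
    """A sample with zero total amount cannot be closed to 100%."""


@dataclass
class PeakTable:
    """Features x samples intensities with feature and sample metadata.

    ``intensities`` is indexed by feature id with one column per sample;
    ``features`` carries at least ``species`` and ``lipid_class`` (plus an
    ``is_standard`` flag); ``samples`` carries ``group`` and
    ``protein_ug``.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.features.index):
            raise ValueError("intensities and features must share an index")
        if not self.intensities.columns.equals(self.samples.index):
            raise ValueError("intensity columns must match the sample index")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        if "is_standard" not in self.features:
            self.features = self.features.assign(is_standard=False)

    @property
    def groups(self) -> pd.Series:
        return self.samples["group"]


@dataclass(frozen=True)
class InternalStandardMap:
    """Per-class spiked standard: species name and amount (ng)."""

    standards: Mapping[str, tuple[str, float]]

    def standard_for(self, lipid_class: str) -> tuple[str, float]:
        try:
            return self.standards[lipid_class]
        except KeyError:
            raise MissingStandard(f"no internal standard mapped for class {lipid_class!r}")


def default_internal_standards() -> InternalStandardMap:
    """The spiked odd-chain standard per class.

    LPC/PC/PE/Cer standards are spiked at 400 ng and TG at 2,000 ng.  The
    ether classes have no dedicated standard and share their diacyl
    counterpart's; SM shares the ceramide standard (nearest sphingolipid).
    Both fallbacks are deliberate defaults and are logged.
    """
    logger.warning(
        "internal-standard fallbacks in effect: PC O- -> PC standard, "
        "PE O- -> PE standard, SM -> Cer standard"
    )
    return InternalStandardMap(
        {
            "LPC": ("LPC(17:0)", 400.0),
            "PC": ("PC(17:0/17:0)", 400.0),
            "PC O-": ("PC(17:0/17:0)", 400.0),
            "PE": ("PE(17:0/17:0)", 400.0),
            "PE O-": ("PE(17:0/17:0)", 400.0),
            "TG": ("TG(17:0/17:0/17:0)", 2000.0),
            "SM": ("Cer(d18:1/17:0)", 400.0),
            "Cer": ("Cer(d18:1/17:0)", 400.0),
        }
    )


def is_normalize(table: PeakTable, is_map: InternalStandardMap | None = None) -> pd.DataFrame:
    """Intensities to ng-equivalent amounts via class standards.

    amount(feature, sample) = intensity / intensity(class standard, sample)
    x spiked amount.  Standards are dropped from the output.  Any standard
    missing or at zero intensity raises :class:`MissingStandard` naming the
    class and sample.
    """
    if is_map is None:
        is_map = default_internal_standards()
    feats = table.features
    std_rows = feats.index[feats["is_standard"].astype(bool)]
    std_by_species = {feats.loc[i, "species"]: i for i in std_rows}

    analyte_rows = feats.index[~feats["is_standard"].astype(bool)]
    amounts = pd.DataFrame(
        index=analyte_rows, columns=table.intensities.columns, dtype=float
    )
    for lipid_class, class_rows in feats.loc[analyte_rows].groupby("lipid_class").groups.items():
        std_name, spiked_ng = is_map.standard_for(str(lipid_class))
        std_idx = std_by_species.get(std_name)
        if std_idx is None:
            raise MissingStandard(
                f"standard {std_name!r} for class {lipid_class!r} not present in table"
            )
        std_intensity = table.intensities.loc[std_idx]
        bad = std_intensity[std_intensity <= 0]
        if len(bad):
            raise MissingStandard(
                f"standard {std_name!r} for class {lipid_class!r} has zero intensity "
                f"in sample(s) {list(bad.index)}"
            )
        amounts.loc[class_rows] = (
            table.intensities.loc[class_rows].div(std_intensity, axis=1) * spiked_ng
        )
    return amounts


def protein_normalize(amounts: pd.DataFrame, protein_ug: pd.Series) -> pd.DataFrame:
    """Amounts per microgram protein (element-wise per-sample division)."""
    protein = protein_ug.reindex(amounts.columns)
    if protein.isna().any() or (protein <= 0).any():
        bad = list(protein.index[protein.isna() | (protein <= 0)])
        raise InvalidProtein(f"non-positive or missing protein amount for {bad}")
    return amounts.div(protein, axis=1)


def _closure(amounts: pd.DataFrame) -> pd.DataFrame:
    totals = amounts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateSample(f"sample(s) with zero total amount: {list(zero.index)}")
    return amounts.div(totals, axis=1) * 100.0


def class_composition(amounts: pd.DataFrame, lipid_class: pd.Series) -> pd.DataFrame:
    """Per-sample % of total lipid per class (closes to 100%)."""
    by_class = amounts.groupby(lipid_class.reindex(amounts.index)).sum()
    return _closure(by_class)


def species_composition(
    amounts: pd.DataFrame,
    lipid_class: pd.Series | None = None,
    scope: str = "total",
) -> pd.DataFrame:
    """Per-sample species %, closed over all species (``total``) or within
    each class (``within-class``, requires ``lipid_class``)."""
    if scope == "total":
        return _closure(amounts)
    if scope == "within-class":
        if lipid_class is None:
            raise ValueError("within-class scope needs a lipid_class series")
        parts = []
        for _, rows in amounts.groupby(lipid_class.reindex(amounts.index)).groups.items():
            parts.append(_closure(amounts.loc[rows]))
        return pd.concat(parts).reindex(amounts.index)
    raise ValueError(f"unknown scope {scope!r}")


@dataclass(frozen=True)
class FattyAcidProfile:
    """Per-sample relative fatty-acid composition (%), closed to 100."""

    composition: pd.DataFrame  # fatty acids x samples, percent
    provenance: str  # "FAME-GC" | "lipidome-decomposition"

    def __post_init__(self) -> None:
        if self.composition.shape[0] == 0:
            return
        sums = self.composition.sum(axis=0)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise ValueError("fatty-acid compositions must sum to 100% per sample")


def fame_composition(
    gc_areas: pd.DataFrame,
    rrf: Mapping[str, float],
    is_name: str,
    is_amount_ug: float,
    strict_rrf: bool = False,
) -> FattyAcidProfile:
    """Relative FAME composition from GC peak areas.

    amount_i = area_i / (rrf_i x area_IS) x spiked IS amount, then closure
    to 100%.  A fatty acid without a response factor defaults to rrf = 1.0
    with a warning (or raises when ``strict_rrf``).
    """
    if is_name not in gc_areas.index:
        raise MissingStandard(f"internal standard {is_name!r} absent from the area table")
    is_area = gc_areas.loc[is_name]
    bad = is_area[is_area <= 0]
    if len(bad):
        raise MissingStandard(
            f"internal standard {is_name!r} has zero area in sample(s) {list(bad.index)}"
        )
    analytes = gc_areas.drop(index=is_name)
    factors = []
    for fa in analytes.index:
        if fa in rrf:
            if rrf[fa] <= 0:
                raise ValueError(f"non-positive response factor for {fa!r}")
            factors.append(rrf[fa])
        elif strict_rrf:
            raise KeyError(f"no response factor for {fa!r}")
        else:
            warnings.warn(f"no response factor for {fa!r}; defaulting to 1.0")
            factors.append(1.0)
    amounts = analytes.div(pd.Series(factors, index=analytes.index), axis=0)
    amounts = amounts.div(is_area, axis=1) * is_amount_ug
    return FattyAcidProfile(composition=_closure(amounts), provenance="FAME-GC")


def lipidome_to_fa_profile(
    amounts: pd.DataFrame,
    species_names: pd.Series | None = None,
) -> FattyAcidProfile:
    """Esterified fatty-acid view of a lipidome amount table.

    Each molecular-acyl species contributes its amount once per
    ester/amide chain occurrence; ether alkyls and sphingoid bases are not
    esterified fatty acids and are skipped, as are species resolved only
    to class totals (with a warning).
    """
    names = species_names if species_names is not None else pd.Series(
        amounts.index, index=amounts.index
    )
    fa_rows: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for feature in amounts.index:
        species = parse_lipid_name(str(names.loc[feature]))
        chains = species.chain_acyls
        if not chains:
            skipped.append(species.name)
            continue
        for acyl in chains:
            fa = acyl.name
            fa_rows.setdefault(fa, np.zeros(amounts.shape[1]))
            fa_rows[fa] = fa_rows[fa] + amounts.loc[feature].to_numpy(dtype=float)
    if skipped:
        warnings.warn(
            f"{len(skipped)} species without resolved chains excluded from the "
            f"fatty-acid decomposition (e.g. {skipped[:3]})"
        )
    if not fa_rows:
        warnings.warn("no acyl-resolved species; empty fatty-acid profile")
        empty = pd.DataFrame(
            np.empty((0, amounts.shape[1])),
            index=pd.Index([], name="fatty_acid"),
            columns=amounts.columns,
        )
        return FattyAcidProfile(composition=empty, provenance="lipidome-decomposition")
    table = pd.DataFrame(fa_rows, index=amounts.columns).T
    table.index.name = "fatty_acid"
    return FattyAcidProfile(composition=_closure(table), provenance="lipidome-decomposition")


def tidy_amounts(
    amounts: pd.DataFrame,
    features: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format (sample, species, class, amount, percent) export."""
    percent = _closure(amounts)
    rows = []
    for feature in amounts.index:
        for sample in amounts.columns:
            rows.append(
                {
                    "sample": sample,
                    "group": samples.loc[sample, "group"],
                    "species": features.loc[feature, "species"],
                    "lipid_class": features.loc[feature, "lipid_class"],
                    "amount": amounts.loc[feature, sample],
                    "percent_of_total": percent.loc[feature, sample],
                }
            )
    return pd.DataFrame(rows)
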
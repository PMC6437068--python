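"""Rule-based assignment of lipid species to MS/MS spectra.

The workflow mirrors a library-search-then-manual-confirmation protocol,
made deterministic: candidate species are proposed by precursor m/z match
against a species library, each candidate is confirmed or rejected by
class-diagnostic fragment evidence (fixed ions and neutral losses from a
packaged, user-editable rule table), and ties among confirmed isobars are
broken by score, then precursor error, then name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .elements import ion_mz, mass_of
from .nomenclature import (
    LipidSpecies,
    adduct_polarity,
    default_adducts,
    species_mz,
)

__all__ = [
    "SpectrumRecord",
    "FragmentSpec",
    "FragmentationRule",
    "IdentificationHit",
    "Candidate",
    "IdentifyConfig",
    "EmptyLibrary",
    "MissingRule",
    "load_fragmentation_rules",
    "candidate_species",
    "confirm_hit",
    "identify_dataset",
    "read_mgf",
    "write_mgf",
]


class EmptyLibrary(ValueError):
    """Candidate search against an empty species library."""


class MissingRule(KeyError):
    """No fragmentation rule registered for a class/polarity pair."""


@dataclass(frozen=True)
class SpectrumRecord:
    """One precursor's MS/MS peak list."""

    precursor_mz: float
    polarity: str  # "+" or "-"
    peaks: tuple[tuple[float, float], ...]  # (m/z, intensity), sorted by m/z
    retention_time: float = 0.0
    title: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")
        mzs = [p[0] for p in self.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))
        if any(not np.isfinite(i) or i < 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be finite and non-negative")

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks], dtype=float)


@dataclass(frozen=True)
class FragmentSpec:
    """A single piece of fragment evidence.

    kind ``ion``/``mz`` is a fixed m/z; kind ``loss`` is a neutral loss,
    resolved against the precursor at match time.
    """

    kind: str  # "ion" | "mz" | "loss"
    value: str | float
    label: str = ""

    def target_mz(self, precursor_mz: float) -> float:
        if self.kind == "mz":
            return float(self.value)
        if self.kind == "ion":
            return ion_mz(str(self.value))
        if self.kind == "loss":
            loss = float(self.value) if not isinstance(self.value, str) else mass_of(self.value)
            return precursor_mz - loss
        raise ValueError(f"unknown fragment kind {self.kind!r}")

    @classmethod
    def from_token(cls, token: str) -> "FragmentSpec":
        kind, _, value = token.partition(":")
        kind = kind.strip()
        value = value.strip()
        if kind not in ("ion", "mz", "loss"):
            raise ValueError(f"bad fragment token {token!r}")
        if kind == "mz":
            return cls(kind="mz", value=float(value), label=token)
        if kind == "loss" and re.fullmatch(r"[\d.]+", value):
            return cls(kind="loss", value=float(value), label=token)
        return cls(kind=kind, value=value, label=token)


@dataclass(frozen=True)
class FragmentationRule:
    lipid_class: str
    polarity: str
    required: tuple[FragmentSpec, ...]
    min_required: int
    forbidden: tuple[FragmentSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.min_required > len(self.required):
            raise ValueError("min_required exceeds number of required fragments")


@dataclass(frozen=True)
class Candidate:
    species: LipidSpecies
    adduct: str
    theoretical_mz: float
    error_ppm: float


@dataclass(frozen=True)
class IdentificationHit:
    species: LipidSpecies
    adduct: str
    precursor_error_ppm: float
    matched_fragments: tuple[str, ...]
    score: float
    status: str  # "confirmed" | "tentative" | "rejected"


@dataclass(frozen=True)
class IdentifyConfig:
    """Tolerances and tie-breaking for dataset identification."""

    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.02


def load_fragmentation_rules(path=None) -> dict[tuple[str, str], FragmentationRule]:
    """Load the packaged (or a user-supplied) fragmentation-rule TSV."""
    if path is None:
        source = resources.files("spherolipid.data") / "fragmentation_rules.tsv"
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t", comment="#")
    else:
        table = pd.read_csv(path, sep="\t", comment="#")
    rules: dict[tuple[str, str], FragmentationRule] = {}
    for row in table.itertuples(index=False):
        required = tuple(FragmentSpec.from_token(t) for t in str(row.required).split(";") if t)
        forbidden_field = "" if pd.isna(row.forbidden) else str(row.forbidden)
        forbidden = tuple(FragmentSpec.from_token(t) for t in forbidden_field.split(";") if t)
        rule = FragmentationRule(
            lipid_class=row.lipid_class,
            polarity=row.polarity,
            required=required,
            min_required=int(row.min_required),
            forbidden=forbidden,
        )
        rules[(rule.lipid_class, rule.polarity)] = rule
    return rules


def candidate_species(
    precursor_mz: float,
    polarity: str,
    library: Sequence[LipidSpecies],
    tol_ppm: float,
    adducts_by_class: Mapping[str, Sequence[str]] | None = None,
) -> list[Candidate]:
    """All (species, adduct) pairs whose theoretical m/z lies within
    ``tol_ppm`` of the precursor, sorted by absolute error.

    Adducts default to each class's packaged defaults for the spectrum
    polarity.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not library:
        raise EmptyLibrary("species library is empty")
    out: list[Candidate] = []
    for species in library:
        if adducts_by_class is not None:
            adducts = [
                a
                for a in adducts_by_class.get(species.lipid_class, ())
                if adduct_polarity(a) == polarity
            ]
        else:
            adducts = list(default_adducts(species.lipid_class, polarity))
        for adduct in adducts:
            theo = species_mz(species, adduct)
            error_ppm = (precursor_mz - theo) / theo * 1e6
            if abs(error_ppm) <= tol_ppm:
                out.append(Candidate(species, adduct, theo, error_ppm))
    out.sort(key=lambda c: (abs(c.error_ppm), c.species.name))
    return out


def _present(spectrum: SpectrumRecord, spec: FragmentSpec, tol_da: float) -> bool:
    if not spectrum.peaks:
        return False
    target = spec.target_mz(spectrum.precursor_mz)
    mzs = spectrum.mz_array
    idx = np.searchsorted(mzs, target)
    for j in (idx - 1, idx):
        if 0 <= j < len(mzs) and abs(mzs[j] - target) <= tol_da:
            return True
    return False


def confirm_hit(
    spectrum: SpectrumRecord,
    candidate: Candidate,
    rules: Mapping[tuple[str, str], FragmentationRule],
    frag_tol_da: float = 0.02,
) -> IdentificationHit:
    """Check a candidate's class-diagnostic fragments against a spectrum.

    Confirmed iff at least ``min_required`` required fragments are present
    and no forbidden fragment is; partially supported candidates are
    tentative; empty evidence or forbidden evidence rejects.
    """
    rule = rules.get((candidate.species.lipid_class, spectrum.polarity))
    if rule is None:
        raise MissingRule(
            f"no fragmentation rule for class {candidate.species.lipid_class!r} "
            f"polarity {spectrum.polarity!r}"
        )
    matched = tuple(
        spec.label or f"{spec.kind}:{spec.value}"
        for spec in rule.required
        if _present(spectrum, spec, frag_tol_da)
    )
    score = len(matched) / len(rule.required) if rule.required else 0.0
    forbidden_hit = any(_present(spectrum, spec, frag_tol_da) for spec in rule.forbidden)
    if forbidden_hit or not matched:
        status = "rejected"
    elif len(matched) >= rule.min_required:
        status = "confirmed"
    else:
        status = "tentative"
    return IdentificationHit(
        species=candidate.species,
        adduct=candidate.adduct,
        precursor_error_ppm=candidate.error_ppm,
        matched_fragments=matched,
        score=score,
        status=status,
    )


def identify_dataset(
    spectra: Sequence[SpectrumRecord],
    library: Sequence[LipidSpecies],
    rules: Mapping[tuple[str, str], FragmentationRule] | None = None,
    config: IdentifyConfig | None = None,
) -> pd.DataFrame:
    """Identify every spectrum against a library.

    Returns an audit table with one row per spectrum-candidate pair
    (``status`` column records the per-candidate outcome) where at most one
    confirmed candidate per spectrum carries ``selected=True``, chosen by
    highest score, then smallest absolute precursor error, then name.
    """
    if rules is None:
        rules = load_fragmentation_rules()
    if config is None:
        config = IdentifyConfig()
    rows = []
    for i, spectrum in enumerate(spectra):
        candidates = candidate_species(
            spectrum.precursor_mz, spectrum.polarity, library, config.precursor_tol_ppm
        )
        hits = [confirm_hit(spectrum, c, rules, config.fragment_tol_da) for c in candidates]
        confirmed = [h for h in hits if h.status == "confirmed"]
        selected_hit = None
        if confirmed:
            selected_hit = min(
                confirmed,
                key=lambda h: (-h.score, abs(h.precursor_error_ppm), h.species.name),
            )
        for hit in hits:
            rows.append(
                {
                    "spectrum_index": i,
                    "title": spectrum.title,
                    "precursor_mz": spectrum.precursor_mz,
                    "polarity": spectrum.polarity,
                    "species": hit.species.name,
                    "lipid_class": hit.species.lipid_class,
                    "adduct": hit.adduct,
                    "error_ppm": hit.precursor_error_ppm,
                    "score": hit.score,
                    "n_matched": len(hit.matched_fragments),
                    "matched_fragments": ";".join(hit.matched_fragments),
                    "status": hit.status,
                    "selected": hit is selected_hit,
                }
            )
    columns = [
        "spectrum_index", "title", "precursor_mz", "polarity", "species",
        "lipid_class", "adduct", "error_ppm", "score", "n_matched",
        "matched_fragments", "status", "selected",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# MGF I/O (pyteomics-backed)
# ---------------------------------------------------------------------------

def read_mgf(path) -> list[SpectrumRecord]:
    """Read spectra from a Mascot generic format file."""
    records = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = params.get("charge")
            polarity = "+"
            if charge:
                polarity = "-" if str(charge[0]).endswith("-") else "+"
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            peaks = tuple(
                (float(m), float(i))
                for m, i in zip(entry["m/z array"], entry["intensity array"])
            )
            records.append(
                SpectrumRecord(
                    precursor_mz=float(params["pepmass"][0]),
                    polarity=polarity,
                    peaks=peaks,
                    retention_time=rt,
                    title=str(params.get("title", "")),
                )
            )
    return records


def write_mgf(spectra: Iterable[SpectrumRecord], path) -> None:
    """Write spectra to MGF, preserving polarity via the CHARGE field."""
    entries = []
    for i, s in enumerate(spectra):
        entries.append(
            {
                "m/z array": np.array([p[0] for p in s.peaks]),
                "intensity array": np.array([p[1] for p in s.peaks]),
                "params": {
                    "title": s.title or f"spectrum_{i}",
                    "pepmass": s.precursor_mz,
                    "charge": "1+" if s.polarity == "+" else "1-",
                    "rtinseconds": s.retention_time * 60.0,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")
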
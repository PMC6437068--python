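"""Plain-text table I/O for the pipeline artifacts.

Peak tables travel as a pair of CSVs (feature rows with metadata plus
sample columns; sample metadata with group and protein), FAME areas as a
single CSV, transcript fold-changes as a two-column TSV.  Spectra use MGF
via :mod:`spherolipid.identify`.
"""

from __future__ import annotations

import pandas as pd

from .pathway import ExpressionOverlay
from .quantify import PeakTable

_FEATURE_META = ["species", "lipid_class", "is_standard"]


def write_peak_table(table: PeakTable, intensities_path, samples_path) -> None:
    meta_cols = [c for c in table.features.columns if c != "species"]
    out = pd.concat(
        [table.features[["species"] + [c for c in ("lipid_class", "is_standard") if c in meta_cols]],
         table.intensities],
        axis=1,
    )
    out.to_csv(intensities_path, index=False)
    table.samples.to_csv(samples_path)


def read_peak_table(intensities_path, samples_path) -> PeakTable:
    wide = pd.read_csv(intensities_path)
    missing = [c for c in _FEATURE_META if c not in wide.columns]
    if missing:
        raise ValueError(f"peak table missing metadata columns {missing}")
    samples = pd.read_csv(samples_path, index_col=0)
    feature_cols = [c for c in wide.columns if c in _FEATURE_META]
    sample_cols = [c for c in wide.columns if c not in _FEATURE_META]
    if list(samples.index) != sample_cols:
        raise ValueError("sample metadata does not match peak-table columns")
    features = wide[feature_cols].copy()
    features.index = pd.Index(wide["species"], name="feature")
    intensities = wide[sample_cols].copy()
    intensities.index = features.index
    return PeakTable(intensities=intensities, features=features, samples=samples)


def write_fame_areas(areas: pd.DataFrame, path) -> None:
    areas.to_csv(path)


def read_fame_areas(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_expression(overlay: ExpressionOverlay, path) -> None:
    pd.DataFrame(
        {"gene": list(overlay.log2fc), "log2fc": list(overlay.log2fc.values())}
    ).to_csv(path, sep="\t", index=False)


def read_expression(path, source: str = "") -> ExpressionOverlay:
    table = pd.read_csv(path, sep="\t")
    if not {"gene", "log2fc"} <= set(table.columns):
        raise ValueError("expression table needs 'gene' and 'log2fc' columns")
    return ExpressionOverlay(
        log2fc=dict(zip(table["gene"].astype(str), table["log2fc"].astype(float))),
        source=source or str(path),
    )
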
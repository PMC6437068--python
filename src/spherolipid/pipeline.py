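"""Orchestration: identify -> quantify -> stats -> pathway -> report.

Each stage consumes and produces plain-text artifacts in the output
directory; the run ends with a JSON summary of the headline quantities
(identified and significant species counts, PLS-DA R2/Q2, VIP >= 1 count,
index directions, gene-index concordance).  A run is a pure function of
(inputs, config, seed): re-running writes byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, dump_config
from .identify import IdentifyConfig, identify_dataset, read_mgf
from .io import (
    read_expression,
    read_fame_areas,
    read_peak_table,
    write_expression,
    write_fame_areas,
    write_peak_table,
)
from .pathway import (
    compare_indices,
    compute_indices,
    concordance,
    default_pathway_map,
    load_pathway_map,
    overlay_expression,
)
from .quantify import (
    class_composition,
    default_internal_standards,
    fame_composition,
    is_normalize,
    protein_normalize,
    species_composition,
)
from .stats import (
    optimal_components,
    pca,
    plsda_fit,
    preprocess,
    q2_cv,
    ttest_bh,
    vip,
)
from .synthgen import (
    FAME_INTERNAL_STANDARD,
    GeneratorConfig,
    default_species_library,
    fame_response_factors,
    generate_expression,
    generate_fame,
    generate_lipidome,
    generate_msms,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def _config_hash(config: PipelineConfig) -> str:
    data = config.to_dict()
    data.pop("out_dir", None)  # where results land is not part of the analysis
    payload = json.dumps(data, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the summary dictionary.

    With ``preset`` set, inputs are simulated from the generator at the
    configured seed; otherwise the files named under ``inputs`` are read.
    Missing input files raise before any stage executes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "spherolipid %s | seed=%d | config=%s", __version__, config.seed,
        _config_hash(config),
    )

    # ------------------------------------------------------------------ inputs
    if config.preset is not None:
        gen = (
            GeneratorConfig() if config.preset == "paper" else GeneratorConfig.null()
        )
        peak_table, lipidome_truth = generate_lipidome(gen, config.seed)
        spectra, msms_truth = generate_msms(
            mass_error_ppm=gen.mass_error_ppm,
            decoy_fraction=gen.decoy_fraction,
            seed=config.seed + 1,
        )
        fame_areas, fame_truth = generate_fame(gen, config.seed + 2)
        expression, expr_truth = generate_expression(gen, config.seed + 3)
        rrf = fame_response_factors()
        write_peak_table(peak_table, out / "peak_table.csv", out / "samples.csv")
        write_fame_areas(fame_areas, out / "fame_areas.csv")
        write_expression(expression, out / "expression.tsv")
    else:
        paths = config.inputs
        required = {
            "peak_table": paths.peak_table,
            "sample_table": paths.sample_table,
            "fame": paths.fame,
            "expression": paths.expression,
        }
        missing = [k for k, v in required.items() if v is None or not Path(v).exists()]
        if missing:
            raise StageError(f"inputs: missing input file(s) {missing}")
        peak_table = read_peak_table(paths.peak_table, paths.sample_table)
        spectra = read_mgf(paths.msms) if paths.msms else None
        fame_areas = read_fame_areas(paths.fame)
        expression = read_expression(paths.expression)
        rrf = fame_response_factors()

    groups = peak_table.samples["group"]

    # ---------------------------------------------------------------- identify
    try:
        if spectra is not None:
            library = default_species_library()
            hits = identify_dataset(
                spectra,
                library,
                config=IdentifyConfig(
                    precursor_tol_ppm=config.identification.precursor_tol_ppm,
                    fragment_tol_da=config.identification.fragment_tol_da,
                ),
            )
            hits.to_csv(out / "identification.tsv", sep="\t", index=False)
            identified = set(hits.loc[hits["selected"], "species"])
        else:
            hits = None
            identified = set(
                peak_table.features.loc[~peak_table.features["is_standard"], "species"]
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"identify: {exc}") from exc

    # ---------------------------------------------------------------- quantify
    try:
        keep = peak_table.features["is_standard"] | peak_table.features[
            "species"
        ].isin(identified)
        table = peak_table
        if not keep.all():
            dropped = int((~keep).sum())
            logger.warning("%d features lack a confirmed identification; dropped", dropped)
            table = type(peak_table)(
                intensities=peak_table.intensities.loc[keep],
                features=peak_table.features.loc[keep],
                samples=peak_table.samples,
            )
        amounts = is_normalize(table, default_internal_standards())
        amounts_pp = protein_normalize(amounts, table.samples["protein_ug"])
        classes = table.features.loc[amounts.index, "lipid_class"]
        class_pct = class_composition(amounts_pp, classes)
        species_pct = species_composition(
            amounts_pp, classes, scope=config.composition.scope
        )
        amounts_pp.to_csv(out / "amounts_per_ug_protein.tsv", sep="\t")
        class_pct.to_csv(out / "class_composition.tsv", sep="\t")
        species_pct.to_csv(out / "species_composition.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"quantify: {exc}") from exc

    # ------------------------------------------------------------------- stats
    try:
        X = species_pct.T  # samples x features
        designed = preprocess(X, groups)
        tests = ttest_bh(
            designed.matrix, groups, alpha=config.stats.alpha, fdr=config.stats.fdr
        )
        tests.table.to_csv(out / "ttest.tsv", sep="\t")
        scores, loadings, evr = pca(designed.matrix, n_components=2)
        scores.to_csv(out / "pca_scores.tsv", sep="\t")
        loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
        n_comp, q2 = optimal_components(
            designed.matrix,
            groups,
            max_components=config.stats.max_components,
            folds=config.stats.folds,
            seed=config.seed,
        )
        model = plsda_fit(designed.matrix, groups, n_components=n_comp)
        vip1 = vip(plsda_fit(designed.matrix, groups, n_components=1))
        vip_table = pd.DataFrame(
            {"vip": vip1}, index=designed.matrix.columns
        ).sort_values("vip", ascending=False)
        vip_table.to_csv(out / "vip.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stats: {exc}") from exc

    # ----------------------------------------------------------------- pathway
    try:
        steps = (
            load_pathway_map(config.pathway.map_path)
            if config.pathway.map_path
            else default_pathway_map()
        )
        profile = fame_composition(
            fame_areas, rrf, FAME_INTERNAL_STANDARD, GeneratorConfig().fame_is_amount_ug
        )
        fame_samples = profile.composition.columns
        if set(fame_samples) <= set(groups.index):
            fame_groups = groups.loc[fame_samples]
        else:  # independent GC-MS sample naming: A*/S* prefix convention
            fame_groups = pd.Series(
                ["Adherent" if s.startswith("A") else "Sphere" for s in fame_samples],
                index=fame_samples,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ratios = compute_indices(profile, steps)
        results = compare_indices(
            ratios, fame_groups, steps, reference="Adherent",
            alpha=config.pathway.alpha,
        )
        annotated, unmatched = overlay_expression(steps, expression)
        conc, conc_p = concordance(
            results, annotated,
            n_permutations=config.pathway.n_permutations, seed=config.seed,
        )
        idx_table = pd.DataFrame(
            {
                "index": [r.step.label for r in results],
                "mean_Adherent": [r.group_means["Adherent"] for r in results],
                "mean_Sphere": [r.group_means["Sphere"] for r in results],
                "t": [r.t for r in results],
                "p": [r.p for r in results],
                "q": [r.q for r in results],
                "direction": [r.direction for r in results],
            }
        )
        idx_table.to_csv(out / "fa_indices.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"pathway: {exc}") from exc

    # ----------------------------------------------------------------- summary
    summary = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_spectra": len(spectra) if spectra is not None else 0,
        "n_identified": len(identified),
        "n_species_tested": int(len(tests.table)),
        "n_significant": tests.n_significant,
        "pca_explained_variance": [round(float(v), 4) for v in evr],
        "plsda_components": model.n_components,
        "plsda_r2y": round(float(model.r2y), 4),
        "plsda_q2": round(float(q2), 4),
        "n_vip_ge_threshold": int((vip1 >= config.stats.vip_threshold).sum()),
        "index_directions": {r.step.label: r.direction for r in results},
        "concordance": round(float(conc), 4),
        "concordance_p": round(float(conc_p), 4),
        "unmatched_overlay_genes": sorted(unmatched),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    dump_config(config, out / "config_used.yaml")
    return summary
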
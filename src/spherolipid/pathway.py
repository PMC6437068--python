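"""Enzyme-mapped fatty-acid indices and transcript-overlay concordance.

Product/substrate composition ratios proxy the activity of desaturation
and elongation steps (e.g. 16:1/16:0 for SCD, 22:6n3/22:5n3 for the
ELOVL2-dependent DHA route).  Indices are compared between groups with
the same pooled t-test used elsewhere, gene log2 fold-changes are
overlaid on the step map, and a permutation test asks whether index
directions agree with the transcript directions more often than chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .quantify import FattyAcidProfile
from .stats import ttest_bh

__all__ = [
    "EnzymeStep",
    "IndexResult",
    "ExpressionOverlay",
    "default_pathway_map",
    "load_pathway_map",
    "write_pathway_map",
    "compute_indices",
    "compare_indices",
    "overlay_expression",
    "concordance",
]

STEP_KINDS = ("desaturation", "elongation", "elongation+b-oxidation")


def _fa_carbons(name: str) -> int:
    return int(name.split(":")[0])


@dataclass(frozen=True)
class EnzymeStep:
    """One substrate -> product conversion with its annotated genes."""

    substrate: str
    product: str
    genes: tuple[str, ...]
    kind: str
    gene_log2fc: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.substrate == self.product:
            raise ValueError("substrate and product must differ")
        if self.kind not in STEP_KINDS:
            raise ValueError(f"unknown step kind {self.kind!r}")
        if self.kind == "elongation":
            if _fa_carbons(self.product) - _fa_carbons(self.substrate) != 2:
                raise ValueError(
                    f"elongation {self.substrate}->{self.product} must add 2 carbons"
                )

    @property
    def label(self) -> str:
        return f"{self.product}/{self.substrate}"

    @property
    def mean_gene_log2fc(self) -> Optional[float]:
        if not self.gene_log2fc:
            return None
        return float(np.mean(list(self.gene_log2fc.values())))


@dataclass(frozen=True)
class IndexResult:
    """Group comparison of one product/substrate index."""

    step: EnzymeStep
    per_sample: pd.Series
    group_means: Mapping[str, float]
    group_sems: Mapping[str, float]
    t: float
    p: float
    q: float
    direction: str  # "up" | "down" | "unchanged"


@dataclass(frozen=True)
class ExpressionOverlay:
    """Gene symbol -> log2 fold-change (case-insensitive lookup)."""

    log2fc: Mapping[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        values = np.array(list(self.log2fc.values()), dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("log2 fold-changes must be finite")

    def lookup(self, symbol: str) -> Optional[float]:
        table = {k.upper(): v for k, v in self.log2fc.items()}
        return table.get(symbol.upper())


def load_pathway_map(path=None) -> list[EnzymeStep]:
    """Read a step map TSV (substrate, product, genes, kind)."""
    if path is None:
        source = resources.files("spherolipid.data") / "pathway_map.tsv"
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t", comment="#")
    else:
        table = pd.read_csv(path, sep="\t", comment="#")
    return [
        EnzymeStep(
            substrate=str(row.substrate),
            product=str(row.product),
            genes=tuple(str(row.genes).split(";")),
            kind=str(row.kind),
        )
        for row in table.itertuples(index=False)
    ]


def write_pathway_map(steps: Sequence[EnzymeStep], path) -> None:
    pd.DataFrame(
        {
            "substrate": [s.substrate for s in steps],
            "product": [s.product for s in steps],
            "genes": [";".join(s.genes) for s in steps],
            "kind": [s.kind for s in steps],
        }
    ).to_csv(path, sep="\t", index=False)


def default_pathway_map() -> list[EnzymeStep]:
    """The packaged unsaturated-FA biosynthesis map (MUFA desaturation,
    saturated elongation chain, FADS1 desaturation, ELOVL2 DHA route)."""
    return load_pathway_map()


def compute_indices(
    profile: FattyAcidProfile, steps: Sequence[EnzymeStep]
) -> pd.DataFrame:
    """Per-sample product/substrate ratios, one row per evaluable step.

    Steps whose substrate or product is absent from the profile are
    skipped with a warning; zero substrate in a sample yields NaN (never
    infinity).
    """
    comp = profile.composition
    rows = {}
    for step in steps:
        if step.substrate not in comp.index or step.product not in comp.index:
            warnings.warn(f"step {step.label}: fatty acid missing from profile; skipped")
            continue
        substrate = comp.loc[step.substrate]
        product = comp.loc[step.product]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = product.where(substrate > 0) / substrate.where(substrate > 0)
        if ratio.isna().any():
            warnings.warn(f"step {step.label}: zero substrate in some samples")
        rows[step.label] = ratio
    return pd.DataFrame(rows).T  # steps x samples


def compare_indices(
    ratios: pd.DataFrame,
    groups: pd.Series,
    steps: Sequence[EnzymeStep],
    reference: str | None = None,
    alpha: float = 0.05,
) -> list[IndexResult]:
    """Two-group comparison of each index.

    Direction is "up"/"down" for the non-reference (treatment) group when
    the pooled t-test clears ``alpha``, else "unchanged".  ``reference``
    defaults to the alphabetically first group label.
    """
    levels = sorted(pd.unique(groups), key=str)
    if reference is None:
        reference = levels[0]
    other = [g for g in levels if g != reference][0]
    test = ttest_bh(ratios.T, groups, alpha=alpha)
    results = []
    step_by_label = {s.label: s for s in steps}
    for label in ratios.index:
        per_sample = ratios.loc[label]
        means = {g: float(per_sample[groups == g].mean()) for g in levels}
        sems = {
            g: float(per_sample[groups == g].std(ddof=1) / np.sqrt((groups == g).sum()))
            for g in levels
        }
        row = test.table.loc[label]
        diff = means[other] - means[reference]
        if row["p"] < alpha and diff != 0:
            direction = "up" if diff > 0 else "down"
        else:
            direction = "unchanged"
        results.append(
            IndexResult(
                step=step_by_label.get(
                    label,
                    EnzymeStep(
                        substrate=label.split("/")[1],
                        product=label.split("/")[0],
                        genes=(),
                        kind="desaturation",
                    ),
                ),
                per_sample=per_sample,
                group_means=means,
                group_sems=sems,
                t=float(row["t"]),
                p=float(row["p"]),
                q=float(row["q"]),
                direction=direction,
            )
        )
    return results


def overlay_expression(
    steps: Sequence[EnzymeStep], expr: ExpressionOverlay
) -> tuple[list[EnzymeStep], list[str]]:
    """Annotate each step with its genes' log2FC (case-insensitive match).

    Returns the annotated steps and the list of overlay genes that matched
    no step.
    """
    step_genes = {g.upper() for s in steps for g in s.genes}
    unmatched = [g for g in expr.log2fc if g.upper() not in step_genes]
    annotated = []
    for step in steps:
        fc = {}
        for gene in step.genes:
            value = expr.lookup(gene)
            if value is not None:
                fc[gene] = float(value)
        annotated.append(replace(step, gene_log2fc=fc or None))
    return annotated, unmatched


def concordance(
    index_results: Sequence[IndexResult],
    annotated_steps: Sequence[EnzymeStep],
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Fraction of steps whose index direction matches the sign of the
    mean annotated gene log2FC, with a permutation p-value.

    The null permutes the gene-annotation-to-step assignment; with a
    single evaluable step there is no exchangeability and p = 1.
    """
    fc_by_label = {
        s.label: s.mean_gene_log2fc
        for s in annotated_steps
        if s.mean_gene_log2fc is not None
    }
    evaluable = [
        r
        for r in index_results
        if r.direction != "unchanged" and r.step.label in fc_by_label
    ]
    if not evaluable:
        raise ValueError("no step has both an index direction and a gene log2FC")
    signs = np.array([1 if r.direction == "up" else -1 for r in evaluable])
    fcs = np.array([fc_by_label[r.step.label] for r in evaluable])
    observed = float(np.mean(signs == np.sign(fcs)))
    if len(evaluable) < 2:
        return observed, 1.0
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(fcs)
        if np.mean(signs == np.sign(perm)) >= observed:
            count += 1
    return observed, (count + 1) / (n_permutations + 1)
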
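"""Integration of per-dataset interaction calls into a landscape.

The landscape is the dataset x gene x score structure obtained by running
the classification pipeline on every dataset of a compendium.  Each call
carries the assigned taxonomy profile, the class probability p, the Bliss
index b and the overall score b*p; datasets are annotated with experiment
metadata (species, cell type, stimuli, time point) and genes with gene
families (checkpoints, interleukins, ...).  Slicing the landscape along
its axes supports frequency summaries, per-family projections and the
context-dependence analysis (which profiles encode a qualitative change of
a focal stimulus's single-agent effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .enrich import GeneSetCollection, hypergeometric_enrichment
from .pipeline import DatasetMeta
from .taxonomy import Taxonomy

#: qualitative change types resolvable from profile categories
CHANGE_TYPES = ("suppression", "antagonistic_reversal",
                "synergistic_reversal", "emergent")

CALL_COLUMNS = ("dataset", "gene", "profile_id", "category", "p", "b",
                "score", "sign")


class LandscapeError(ValueError):
    pass


@dataclass
class Landscape:
    """Calls indexed by (dataset, gene) plus annotations."""

    calls: pd.DataFrame
    metas: dict[str, DatasetMeta]
    gene_families: dict[str, frozenset] = field(default_factory=dict)
    taxonomy: Taxonomy | None = None

    @property
    def datasets(self) -> list[str]:
        return sorted(self.metas)

    @property
    def n_calls(self) -> int:
        return len(self.calls)

    @property
    def n_interactions(self) -> int:
        """Calls assigned to an interacting (sign != 0) profile."""
        return int((self.calls["sign"] != 0).sum())


def build_landscape(call_tables: Mapping[str, pd.DataFrame],
                    metas: Mapping[str, DatasetMeta],
                    gene_families: Mapping[str, Iterable] | None = None,
                    taxonomy: Taxonomy | None = None) -> Landscape:
    """Concatenate per-dataset call tables into one queryable landscape.

    ``call_tables`` maps a unique dataset id to the pipeline's calls table;
    every dataset id must have metadata.
    """
    ids = list(call_tables)
    if len(set(ids)) != len(ids):  # pragma: no cover - dict keys unique
        raise LandscapeError("duplicate dataset ids")
    missing = [d for d in ids if d not in metas]
    if missing:
        raise LandscapeError(f"datasets without metadata: {missing}")
    frames = []
    for ds, table in call_tables.items():
        frame = table.copy()
        frame.insert(0, "dataset", ds)
        frames.append(frame)
    calls = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=list(CALL_COLUMNS)))
    if not calls.empty and not calls["score"].map(
            lambda s: s == s and abs(s) != float("inf")).all():
        raise LandscapeError("non-finite interaction scores")
    families = {name: frozenset(genes)
                for name, genes in (gene_families or {}).items()}
    return Landscape(calls=calls, metas=dict(metas),
                     gene_families=families, taxonomy=taxonomy)


def profile_frequencies(landscape: Landscape) -> pd.Series:
    """Proportion of interacting calls per profile category.

    The denominator is the number of calls whose profile has a nonzero
    interaction sign; additive/constant calls are excluded.  Categories
    with no calls are reported as 0.  Proportions sum to 1.
    """
    interacting = landscape.calls[landscape.calls["sign"] != 0]
    if interacting.empty:
        raise LandscapeError("landscape has no interacting calls")
    counts = interacting["category"].value_counts()
    categories = [c for c in
                  ("emergent", "potentiation", "inhibition", "suppression",
                   "restoration", "ceiling", "floor", "synergistic_reversal",
                   "antagonistic_reversal")]
    freq = pd.Series({c: counts.get(c, 0) / len(interacting)
                      for c in categories}, name="proportion")
    return freq


def slice_landscape(landscape: Landscape, gene_family: str,
                    dataset_filter: Sequence[str] | None = None
                    ) -> pd.DataFrame:
    """2D projection gene x dataset for one gene family.

    Rows are family genes with at least one call in the filtered datasets;
    cells are dicts with score magnitude, sign and profile id (NaN when the
    gene was not called in that dataset).  An empty ``dataset_filter``
    selects all datasets.
    """
    if gene_family not in landscape.gene_families:
        raise LandscapeError(f"unknown gene family {gene_family!r}")
    datasets = list(dataset_filter) if dataset_filter else landscape.datasets
    unknown = set(datasets) - set(landscape.metas)
    if unknown:
        raise LandscapeError(f"unknown datasets {sorted(unknown)}")
    family = landscape.gene_families[gene_family]
    sub = landscape.calls[
        landscape.calls["gene"].isin(family)
        & landscape.calls["dataset"].isin(datasets)]
    table = pd.DataFrame(index=sorted(sub["gene"].unique()),
                         columns=datasets, dtype=object)
    for _, row in sub.iterrows():
        table.at[row["gene"], row["dataset"]] = {
            "score": abs(row["score"]), "sign": row["sign"],
            "profile_id": row["profile_id"]}
    table.index.name = "gene"
    return table


def qualitative_change_analysis(landscape: Landscape, focal_role: str,
                                change_types: Sequence[str] = CHANGE_TYPES
                                ) -> dict[tuple[str, str], list[str]]:
    """Genes whose profile encodes a qualitative change of the focal
    stimulus's single-agent effect, per (dataset, change type).

    ``focal_role`` says which design role ('X' or 'Y') the stimulus of
    interest plays.  A profile contributes when its category matches the
    change type and its target (the stimulus whose effect is altered)
    includes the focal role.  For 'emergent' the combination creates an
    effect absent from both single agents, so every dataset's emergent
    calls are reported regardless of role.
    """
    if focal_role not in ("X", "Y"):
        raise LandscapeError("focal_role must be 'X' or 'Y'")
    bad = set(change_types) - set(CHANGE_TYPES)
    if bad:
        raise LandscapeError(f"unsupported change types {sorted(bad)}")
    if landscape.taxonomy is None:
        raise LandscapeError("landscape carries no taxonomy reference")
    targets = {p.id: p.target for p in landscape.taxonomy.profiles}
    out: dict[tuple[str, str], list[str]] = {}
    for ds in landscape.datasets:
        sub = landscape.calls[landscape.calls["dataset"] == ds]
        for change in change_types:
            mask = sub["category"] == change
            genes = [
                g for g, pid in zip(sub.loc[mask, "gene"],
                                    sub.loc[mask, "profile_id"])
                if targets[int(pid)] in (focal_role, "both")]
            out[(ds, change)] = sorted(genes)
    return out


def emergent_functions(combo_gene_list: Iterable,
                       mono_regulated_genes: Iterable,
                       gene_sets: GeneSetCollection,
                       universe: Iterable,
                       **enrich_kwargs) -> pd.DataFrame:
    """Functions enriched in the combination-specific gene list but not in
    the genes regulated by the focal stimulus alone: candidate emergent
    functions created by the interaction."""
    combo = set(combo_gene_list)
    mono = set(mono_regulated_genes)
    universe = set(universe)
    if not universe:
        raise LandscapeError("empty universe")
    combo_hits = hypergeometric_enrichment(combo, universe, gene_sets,
                                           **enrich_kwargs)
    combo_sig = combo_hits[combo_hits["significant"]]
    if mono:
        mono_hits = hypergeometric_enrichment(mono, universe, gene_sets,
                                              **enrich_kwargs)
        mono_sig = set(mono_hits.loc[mono_hits["significant"], "term"])
    else:
        mono_sig = set()
    return combo_sig[~combo_sig["term"].isin(mono_sig)].reset_index(drop=True)
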
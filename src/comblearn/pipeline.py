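"""End-to-end per-dataset analysis: filtering, classification, scoring.

The analysis of one combination-treatment dataset proceeds through a fixed
stage order:

1. probe collapse -- for genes measured by several probes, keep the probe
   with the largest coefficient of variation;
2. CV filter -- drop genes with coefficient of variation below the median
   across genes (CV is computed on the linear scale, 2**x, to avoid sign
   pathologies of log-scale means);
3. differential-expression gate -- moderated omnibus 4-group F test,
   Benjamini-Hochberg adjusted p < alpha;
4. signal filter -- among differentially expressed genes, drop those with
   estimated signal delta below the median;
5. classification and scoring -- the surviving genes are assigned a
   taxonomy profile and class probability p by the classifier; the Bliss
   index b = (eXY - e0) - ((eX - e0) + (eY - e0)) measures interaction
   magnitude and the overall interaction score is the product b * p.

Re-running with identical inputs, configuration and seed is bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .classify import TrainedClassifier
from .features import featurize
from .taxonomy import Taxonomy, bliss_index

CONDITIONS = ("CTRL", "X", "Y", "COMBO")


class PipelineError(ValueError):
    pass


@dataclass
class DatasetMeta:
    accession: str
    species: str = ""
    cell_type: str = ""
    signal_x: str = ""
    signal_y: str = ""
    time_point: str = ""

    def __post_init__(self):
        if not self.accession:
            raise PipelineError("accession must be nonempty")


@dataclass
class DatasetBundle:
    """One dataset: log2 expression matrix, design, optional probe map."""

    expression: pd.DataFrame          # rows: probes/genes, cols: samples
    design: pd.Series                 # sample -> condition
    probe_map: pd.Series | None = None  # probe -> gene
    meta: DatasetMeta | None = None

    def __post_init__(self):
        missing = [c for c in CONDITIONS
                   if (self.design == c).sum() < 2]
        if missing:
            raise PipelineError(
                "conditions with fewer than 2 samples: " + ", ".join(missing))
        unknown = set(self.design.unique()) - set(CONDITIONS)
        if unknown:
            raise PipelineError(f"unknown condition tokens {sorted(unknown)}")
        extra = set(self.design.index) - set(self.expression.columns)
        if extra:
            raise PipelineError(f"design samples missing from the "
                                f"expression matrix: {sorted(extra)}")

    def replicate_array(self) -> tuple[np.ndarray, pd.Index]:
        """(n_genes, 4, n_reps) array in condition order CTRL, X, Y, COMBO.

        Unequal replicate counts are truncated to the smallest group size
        so the array is rectangular.
        """
        groups = {c: self.design.index[self.design == c] for c in CONDITIONS}
        n = min(len(g) for g in groups.values())
        mats = [self.expression[groups[c][:n]].to_numpy() for c in CONDITIONS]
        arr = np.stack(mats, axis=1)
        return arr, self.expression.index


@dataclass
class RunConfig:
    """Thresholds for the per-dataset analysis."""

    alpha: float = 0.05
    cv_filter: bool = True
    delta_filter: bool = True
    tau: float = 0.0          # nonzero-difference threshold for delta-hat
    seed: int = 0


def linear_cv(matrix: pd.DataFrame) -> pd.Series:
    """Coefficient of variation per gene on the linear (2**x) scale."""
    linear = np.power(2.0, matrix.to_numpy(dtype=float))
    mean = linear.mean(axis=1)
    sd = linear.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    return pd.Series(cv, index=matrix.index)


def collapse_probes(matrix: pd.DataFrame,
                    probe_map: pd.Series) -> pd.DataFrame:
    """One row per gene: the probe with the largest coefficient of
    variation among the gene's probes (ties keep the first probe in input
    order, with a warning)."""
    if probe_map is None or len(probe_map) == 0:
        raise PipelineError("empty probe map")
    covered = matrix.index.intersection(probe_map.index)
    dropped = len(matrix) - len(covered)
    if dropped:
        warnings.warn(f"{dropped} probes not covered by the probe map "
                      "were dropped")
    sub = matrix.loc[covered]
    cv = linear_cv(sub)
    chosen = []
    for gene, probes in probe_map.loc[covered].groupby(probe_map):
        idx = probes.index
        cvs = cv.loc[idx]
        best = cvs.max()
        winners = idx[(cvs == best).to_numpy()]
        if len(winners) > 1:
            warnings.warn(f"gene {gene}: CV tie among probes "
                          f"{list(winners)}; keeping {winners[0]}")
        chosen.append((gene, winners[0]))
    out = pd.DataFrame(
        {gene: sub.loc[probe] for gene, probe in chosen}).T
    out.columns = matrix.columns
    out.index.name = "gene"
    return out.sort_index()


def filter_low_cv(matrix: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with coefficient of variation >= the median CV."""
    if len(matrix) < 2:
        raise PipelineError("CV filter needs >= 2 genes")
    cv = linear_cv(matrix)
    if cv.max() == 0:
        raise PipelineError("all-constant matrix: CV filter undefined")
    return matrix.loc[cv >= cv.median()]


def differential_genes(matrix: pd.DataFrame, design: pd.Series,
                       alpha: float = 0.05,
                       tau: float = 0.0) -> tuple[pd.Index, pd.DataFrame]:
    """Genes whose moderated omnibus 4-group test passes BH-adjusted
    p < alpha.  Returns (gene index, full feature table for all genes)."""
    if len(matrix) == 0:
        raise PipelineError("empty expression matrix")
    bundle = DatasetBundle(expression=matrix, design=design)
    reps, genes = bundle.replicate_array()
    table, _ = featurize(reps, moderation="auto", tau=tau)
    table.index = genes
    adj = multipletests(table["omnibus_p"].to_numpy(), method="fdr_bh")[1]
    table["omnibus_p_adj"] = adj
    return genes[adj < alpha], table


def filter_by_delta(de_genes: pd.Index,
                    feature_table: pd.DataFrame) -> pd.Index:
    """Among DE genes, keep those with delta-hat >= the median delta-hat."""
    if len(de_genes) == 0:
        raise PipelineError("empty differential gene set")
    deltas = feature_table.loc[de_genes, "delta_hat"]
    return de_genes[(deltas >= deltas.median()).to_numpy()]


def interaction_score(b: float, p: float) -> float:
    """Overall interaction score b * p (magnitude times class probability)."""
    if not 0.0 <= p <= 1.0:
        raise PipelineError(f"class probability {p} outside [0, 1]")
    return b * p


def run_dataset(bundle: DatasetBundle, model: TrainedClassifier,
                taxonomy: Taxonomy,
                config: RunConfig | None = None
                ) -> tuple[pd.DataFrame, dict]:
    """Full per-dataset analysis; returns (calls table, run manifest).

    The calls table has one row per gene surviving all filters: gene,
    profile_id, category, p, b, score, sign.  Genes assigned to
    non-interacting profiles are retained with sign 0.  The manifest
    records the gene count after each stage.
    """
    config = config or RunConfig()
    counts = {}
    matrix = bundle.expression
    counts["input"] = len(matrix)
    if bundle.probe_map is not None:
        matrix = collapse_probes(matrix, bundle.probe_map)
    counts["after_probe_collapse"] = len(matrix)
    if config.cv_filter:
        matrix = filter_low_cv(matrix)
    counts["after_cv_filter"] = len(matrix)
    de_genes, table = differential_genes(matrix, bundle.design,
                                         alpha=config.alpha, tau=config.tau)
    counts["after_de_filter"] = len(de_genes)
    if config.delta_filter and len(de_genes):
        de_genes = filter_by_delta(de_genes, table)
    counts["after_delta_filter"] = len(de_genes)

    feature_cols = [c for c in table.columns if c != "omnibus_p_adj"]
    rows = []
    if len(de_genes):
        feats = table.loc[de_genes, feature_cols]
        pids, probs = model.predict(feats)
        means = feats.iloc[:, :4].to_numpy()
        for gene, pid, p, mv in zip(de_genes, pids, probs, means):
            b = bliss_index(mv)
            profile_sign = taxonomy.interaction_sign_of(int(pid))
            sign = int(np.sign(b)) if profile_sign != 0 else 0
            if profile_sign != 0 and sign != profile_sign:
                warnings.warn(
                    f"gene {gene}: Bliss sign {sign} disagrees with "
                    f"profile {pid} sign {profile_sign}")
            rows.append({
                "gene": gene, "profile_id": int(pid),
                "category": taxonomy.category_of(int(pid)),
                "p": float(p), "b": float(b),
                "score": interaction_score(float(b), float(p)),
                "sign": sign,
            })
    calls = pd.DataFrame(
        rows, columns=["gene", "profile_id", "category", "p", "b",
                       "score", "sign"])
    counts["calls"] = len(calls)
    counts["interacting_calls"] = int((calls["sign"] != 0).sum()) \
        if len(calls) else 0
    manifest = {
        "stage_counts": counts,
        "config": {"alpha": config.alpha, "cv_filter": config.cv_filter,
                   "delta_filter": config.delta_filter, "tau": config.tau,
                   "seed": config.seed},
        "model_kind": model.model_kind,
    }
    if bundle.meta is not None:
        manifest["accession"] = bundle.meta.accession
    return calls, manifest
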
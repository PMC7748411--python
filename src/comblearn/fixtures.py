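"""Fully synthetic combination-treatment datasets with known ground truth.

Every pipeline stage is testable without downloads: this module composes
the profile simulator into dataset-shaped fixtures (expression matrix +
design + truth table), generates gene-set collections with a planted
enriched term, and exposes the packaged compendium metadata table.

Gene names are synthetic tokens (G000001, ...); an optional immune-gene
alias list lets gene-family slicing be exercised with familiar symbols.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import simulate
from .enrich import GeneSetCollection
from .pipeline import CONDITIONS, DatasetMeta
from .taxonomy import CATEGORIES, Taxonomy, default_taxonomy

#: pinned checksum of the packaged compendium transcription
COMPENDIUM_SHA256 = \
    "acb457e4de581f549bfec535366440a81b03f5aeee74dad15aa5788fcb0955df"


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# compendium metadata


def compendium_path() -> Path:
    return Path(resources.files("comblearn.data") / "compendium.tsv")


def compendium_table() -> pd.DataFrame:
    """The packaged combination-treatment compendium metadata.

    32 datasets (25 human, 7 murine): accession, species, cell type, the
    two stimuli and the time point.  The packaged file is checksummed.
    """
    path = compendium_path()
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != COMPENDIUM_SHA256:
        raise FixtureError("packaged compendium checksum mismatch")
    return pd.read_csv(path, sep="\t", dtype=str)


def compendium_metas() -> dict[str, DatasetMeta]:
    """DatasetMeta per compendium row, keyed by a unique dataset id
    (accession + stimuli + time point, since accessions repeat)."""
    out = {}
    for _, row in compendium_table().iterrows():
        key = f"{row.accession}:{row.signal_x}+{row.signal_y}@{row.time_point}"
        out[key] = DatasetMeta(
            accession=row.accession, species=row.species,
            cell_type=row.cell_type, signal_x=row.signal_x,
            signal_y=row.signal_y, time_point=row.time_point)
    return out


def gene_families() -> dict[str, frozenset]:
    """Packaged synthetic gene-family annotation (editable TSV)."""
    path = Path(resources.files("comblearn.data")
                / "gene_families_synthetic.tsv")
    table = pd.read_csv(path, sep="\t")
    return {fam: frozenset(sub["gene"])
            for fam, sub in table.groupby("family")}


# ---------------------------------------------------------------------------
# synthetic datasets


@dataclass
class SyntheticDataset:
    """Expression matrix, design and per-gene ground truth."""

    expression: pd.DataFrame
    design: pd.Series
    truth: pd.DataFrame   # gene, profile_id, category, means, delta, regime


def _allocate(n_genes: int, mix: Mapping) -> list[tuple[object, int]]:
    """Deterministic largest-remainder allocation of genes to mix keys."""
    keys = list(mix)
    props = np.array([float(mix[k]) for k in keys])
    if np.any(props < 0) or not np.isclose(props.sum(), 1.0):
        raise FixtureError("profile mix proportions must be >= 0 and sum "
                           "to 1")
    raw = props * n_genes
    counts = np.floor(raw).astype(int)
    short = n_genes - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:short]:
        counts[i] += 1
    return [(k, int(c)) for k, c in zip(keys, counts)]


def _resolve_mix_key(key, taxonomy: Taxonomy) -> list[int]:
    """A mix key is a profile id (int) or a category name (str)."""
    if isinstance(key, (int, np.integer)):
        taxonomy[int(key)]
        return [int(key)]
    if key in CATEGORIES:
        ids = [p.id for p in taxonomy.profiles_in_category(key)]
        if not ids:
            raise FixtureError(f"category {key!r} has no profiles")
        return ids
    raise FixtureError(f"invalid profile mix key {key!r}")


def generate_synthetic_dataset(n_genes: int, profile_mix: Mapping,
                               regime=4.0, n_reps: int = 4, seed: int = 0,
                               taxonomy: Taxonomy | None = None
                               ) -> SyntheticDataset:
    """A dataset-shaped fixture with known per-gene truth.

    ``profile_mix`` maps profile ids or category names to proportions
    (summing to 1); allocation of gene counts to keys is deterministic
    (largest remainder), the profile drawn within a category is random.
    The expression matrix has 4 * n_reps sample columns labeled by
    condition; noise follows the delta/sigma regime.  Same seed, same
    files.
    """
    if n_genes < 1:
        raise FixtureError("n_genes must be >= 1")
    tax = taxonomy or default_taxonomy()
    rng = np.random.default_rng(seed)
    ratio = simulate.resolve_regime(regime)
    jobs: list[int] = []
    for key, count in _allocate(n_genes, profile_mix):
        ids = _resolve_mix_key(key, tax)
        jobs.extend(int(rng.choice(ids)) for _ in range(count))

    samplers: dict[int, simulate._ProfileSampler] = {}
    rows: list = [None] * n_genes
    truth_rows: list = [None] * n_genes
    sigma_pool: list[float] = []
    constants: list[int] = []
    for gi, pid in enumerate(jobs):
        profile = tax[pid]
        if profile.category == "constant":
            constants.append(gi)
            continue
        if pid not in samplers:
            samplers[pid] = simulate._ProfileSampler(profile)
        v = samplers[pid].sample(1, rng)[0]
        delta = simulate.signal_delta(v)
        sigma = delta / ratio
        sigma_pool.append(sigma)
        reps = simulate.add_noise(v, ratio, n_reps, rng)
        rows[gi] = reps.ravel()
        truth_rows[gi] = (pid, profile.category, *v, delta, sigma)
    for gi in constants:
        profile = tax[jobs[gi]]
        if jobs[gi] not in samplers:
            samplers[jobs[gi]] = simulate._ProfileSampler(profile)
        v = samplers[jobs[gi]].sample(1, rng)[0]
        # non-responsive genes carry typical residual noise of normalized
        # array data (0.1-0.5 log2), not the signal-scaled sigma of
        # responsive genes
        sigma = float(rng.uniform(0.1, 0.5))
        reps = simulate.add_noise(v, ratio, n_reps, rng, sigma=sigma)
        rows[gi] = reps.ravel()
        truth_rows[gi] = (jobs[gi], "constant", *v, np.nan, sigma)

    genes = [f"G{i + 1:06d}" for i in range(n_genes)]
    samples = [f"{c}_{r + 1}" for c in CONDITIONS for r in range(n_reps)]
    expression = pd.DataFrame(np.vstack(rows), index=genes, columns=samples)
    expression.index.name = "gene"
    design = pd.Series({s: s.rsplit("_", 1)[0] for s in samples},
                       name="condition")
    design.index.name = "sample"
    truth = pd.DataFrame(
        truth_rows, index=genes,
        columns=["profile_id", "category", "e0", "eX", "eY", "eXY",
                 "delta", "sigma"])
    truth.insert(0, "regime", ratio)
    truth.index.name = "gene"
    return SyntheticDataset(expression=expression, design=design,
                            truth=truth)


def generate_planted_gmt(truth: pd.DataFrame, n_terms: int,
                         planted_size: int = 20,
                         background_size: int = 20,
                         seed: int = 0,
                         name: str = "synthetic") -> GeneSetCollection:
    """A GMT collection with one term planted on interacting truth genes.

    The planted term ('PLANTED') draws ``planted_size`` genes from the
    interacting (sign != 0 category) truth genes; ``n_terms`` background
    terms draw uniformly from all genes.
    """
    rng = np.random.default_rng(seed)
    interacting = truth.index[
        ~truth["category"].isin(["constant", "additive"])]
    pool = list(truth.index)
    if planted_size > len(interacting):
        raise FixtureError(
            f"planted term size {planted_size} exceeds the "
            f"{len(interacting)} interacting genes available")
    if background_size > len(pool):
        raise FixtureError("background term size exceeds the gene pool")
    terms = {"PLANTED": frozenset(
        rng.choice(interacting, planted_size, replace=False))}
    for i in range(n_terms):
        terms[f"TERM{i + 1:03d}"] = frozenset(
            rng.choice(pool, background_size, replace=False))
    return GeneSetCollection(name=name, terms=terms)
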
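"""Landscape integration: frequencies, slicing, context-dependence."""

import numpy as np
import pandas as pd
import pytest

from comblearn import enrich as en
from comblearn import landscape as ls
from comblearn.pipeline import DatasetMeta


def _calls(rows):
    return pd.DataFrame(rows, columns=["gene", "profile_id", "category",
                                       "p", "b", "score", "sign"])


def _call(gene, pid, category, sign, score=1.0):
    return (gene, pid, category, 0.9, score / 0.9, score, sign)


@pytest.fixture
def toy_landscape(taxonomy):
    d1 = _calls([_call("g1", 3, "emergent", 1, 2.0),
                 _call("g2", 14, "additive", 0, 0.5),
                 _call("g3", 60, "suppression", -1, -1.5)])
    d2 = _calls([_call("g1", 3, "emergent", 1, 1.0),
                 _call("g4", 40, "potentiation", 1, 3.0)])
    metas = {"dsA": DatasetMeta(accession="dsA", signal_x="TNF",
                                signal_y="IFNb"),
             "dsB": DatasetMeta(accession="dsB", signal_x="TNF",
                                signal_y="IFNg")}
    return ls.build_landscape(
        {"dsA": d1, "dsB": d2}, metas,
        gene_families={"fam1": {"g1", "g4"}, "empty_fam": set()},
        taxonomy=taxonomy)


def test_build_landscape_counts(toy_landscape):
    assert toy_landscape.n_calls == 5
    assert toy_landscape.n_interactions == 4
    assert toy_landscape.datasets == ["dsA", "dsB"]


def test_build_landscape_requires_metadata(taxonomy):
    with pytest.raises(ls.LandscapeError, match="without metadata"):
        ls.build_landscape({"ds": _calls([])},
                           {"other": DatasetMeta(accession="other")})


def test_profile_frequencies_sum_to_one(toy_landscape):
    freq = ls.profile_frequencies(toy_landscape)
    assert freq.sum() == pytest.approx(1.0)
    assert freq["emergent"] == pytest.approx(2 / 4)
    assert freq["suppression"] == pytest.approx(1 / 4)
    assert freq["ceiling"] == 0.0


def test_profile_frequencies_recover_planted_mix(taxonomy):
    """Category proportions of a random landscape are recovered within
    multinomial error."""
    rng = np.random.default_rng(0)
    probs = {"emergent": 0.5, "suppression": 0.3, "potentiation": 0.2}
    rows = []
    for i in range(2000):
        cat = rng.choice(list(probs), p=list(probs.values()))
        pid = rng.choice([p.id for p in
                          taxonomy.profiles_in_category(cat)])
        sign = taxonomy.interaction_sign_of(int(pid))
        rows.append(_call(f"g{i}", int(pid), cat, sign))
    land = ls.build_landscape({"ds": _calls(rows)},
                              {"ds": DatasetMeta(accession="ds")},
                              taxonomy=taxonomy)
    freq = ls.profile_frequencies(land)
    for cat, p in probs.items():
        assert freq[cat] == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p)
                                                             / 2000))


def test_slice_projects_family_by_dataset(toy_landscape):
    table = ls.slice_landscape(toy_landscape, "fam1")
    assert list(table.index) == ["g1", "g4"]
    assert list(table.columns) == ["dsA", "dsB"]
    assert table.at["g1", "dsA"]["score"] == pytest.approx(2.0)
    assert table.at["g1", "dsB"]["sign"] == 1
    assert pd.isna(table.at["g4", "dsA"])
    only_a = ls.slice_landscape(toy_landscape, "fam1",
                                dataset_filter=["dsA"])
    assert list(only_a.columns) == ["dsA"]
    with pytest.raises(ls.LandscapeError, match="unknown gene family"):
        ls.slice_landscape(toy_landscape, "nope")


def test_slicing_is_lossless(toy_landscape):
    """The union of single-dataset slices over a family covering all genes
    reconstructs the interacting call set."""
    toy_landscape.gene_families["all"] = frozenset(
        toy_landscape.calls["gene"])
    seen = set()
    for ds in toy_landscape.datasets:
        table = ls.slice_landscape(toy_landscape, "all",
                                   dataset_filter=[ds])
        for gene in table.index:
            if isinstance(table.at[gene, ds], dict):
                seen.add((ds, gene))
    expected = set(zip(toy_landscape.calls["dataset"],
                       toy_landscape.calls["gene"]))
    assert seen == expected


def test_qualitative_change_routing(taxonomy):
    """A profile encoding suppression of X routes under focal X but not
    focal Y; emergent calls route under both roles."""
    supp_x = next(p for p in taxonomy.profiles
                  if p.category == "suppression" and p.target == "X")
    rows = [_call("gS", supp_x.id, "suppression",
                  supp_x.interaction_sign),
            _call("gE", 3, "emergent", 1)]
    land = ls.build_landscape({"ds": _calls(rows)},
                              {"ds": DatasetMeta(accession="ds")},
                              taxonomy=taxonomy)
    focal_x = ls.qualitative_change_analysis(land, "X")
    focal_y = ls.qualitative_change_analysis(land, "Y")
    assert focal_x[("ds", "suppression")] == ["gS"]
    assert focal_y[("ds", "suppression")] == []
    assert focal_x[("ds", "emergent")] == ["gE"]
    assert focal_y[("ds", "emergent")] == ["gE"]
    assert focal_x[("ds", "antagonistic_reversal")] == []
    with pytest.raises(ls.LandscapeError):
        ls.qualitative_change_analysis(land, "Z")
    with pytest.raises(ls.LandscapeError):
        ls.qualitative_change_analysis(land, "X", ["inhibition"])


def test_role_swap_involution(taxonomy):
    """Relabeling X<->Y (profiles mapped to their mirrors) then analyzing
    focal X equals analyzing focal Y on the original landscape."""
    rng = np.random.default_rng(5)
    pool = [p for p in taxonomy.profiles
            if p.category in ("suppression", "synergistic_reversal",
                              "antagonistic_reversal", "emergent")]
    rows = []
    for i, p in enumerate(rng.choice(pool, 30)):
        rows.append(_call(f"g{i}", p.id, p.category, p.interaction_sign))
    metas = {"ds": DatasetMeta(accession="ds")}
    land = ls.build_landscape({"ds": _calls(rows)}, metas,
                              taxonomy=taxonomy)
    swapped_rows = []
    for row in rows:
        mid = taxonomy.mirror_id(row[1])
        swapped_rows.append((row[0], mid, taxonomy.category_of(mid),
                             *row[3:]))
    swapped = ls.build_landscape({"ds": _calls(swapped_rows)}, metas,
                                 taxonomy=taxonomy)
    out_swapped_x = ls.qualitative_change_analysis(swapped, "X")
    out_orig_y = ls.qualitative_change_analysis(land, "Y")
    assert out_swapped_x == out_orig_y


def test_emergent_functions_excludes_mono_terms():
    universe = [f"g{i}" for i in range(300)]
    combo = universe[:40]
    mono = universe[100:140]
    coll = en.GeneSetCollection("t", {
        "COMBO_ONLY": frozenset(universe[:20]),
        "SHARED": frozenset(universe[:10] + universe[100:110]),
        "NEITHER": frozenset(universe[200:220]),
    })
    out = ls.emergent_functions(combo, mono, coll, universe)
    assert "COMBO_ONLY" in set(out["term"])
    assert "SHARED" not in set(out["term"])
    assert "NEITHER" not in set(out["term"])
    # empty mono list: every combo-enriched term is reported
    out2 = ls.emergent_functions(combo, [], coll, universe)
    assert "SHARED" in set(out2["term"])
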
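"""Taxonomy structure, matching semantics and partition properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comblearn import taxonomy as tx


def test_packaged_taxonomy_loads_123_validated_profiles(taxonomy):
    assert len(taxonomy) == 123
    assert taxonomy.ids == list(range(1, 124))
    # every profile is satisfiable: a strictly feasible witness exists
    for pid in taxonomy.ids:
        w = taxonomy.witness(pid)
        assert taxonomy[pid].satisfies(w, 1e-9)


def test_enumerator_reproduces_packaged_definition(taxonomy):
    """The first-principles enumerator is an independent cross-check of the
    packaged definition file."""
    generated = tx.enumerate_profiles()
    assert len(generated) == 123
    by_id = {p.id: p for p in generated}
    for p in taxonomy.profiles:
        q = by_id[p.id]
        assert (p.name, p.category, p.interaction_sign, p.target) == \
            (q.name, q.category, q.interaction_sign, q.target)
        assert [r.to_string() for r in p.relations] == \
            [r.to_string() for r in q.relations]


def test_emergent_synergy_anchor_vectors(taxonomy):
    """The emergent-synergy system (profile 3) accepts the documented
    instances and rejects the all-equal vector."""
    p3 = taxonomy[3]
    assert p3.category == "emergent"
    assert p3.interaction_sign == 1
    assert tx.satisfies(p3, (2.2, 2.2, 2.2, 5.5))
    assert tx.satisfies(p3, (4.1, 4.1, 4.1, 7.8))
    assert not tx.satisfies(p3, (0.0, 0.0, 0.0, 0.0))
    assert taxonomy[1].satisfies((0.0, 0.0, 0.0, 0.0))


def test_category_and_sign_queries(taxonomy):
    assert taxonomy.category_of(3) == "emergent"
    assert taxonomy.interaction_sign_of(3) == 1
    additive = taxonomy.profiles_in_category("additive")
    assert additive and all(p.interaction_sign == 0 for p in additive)
    with pytest.raises(KeyError):
        taxonomy.category_of(999)


def test_unsatisfiable_profile_rejected_at_load(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "1\tcontradiction\tadditive\t0\tnone\t"
        "+e0-eX<0 ; +eX-e0<0 ; +e0-eX-eY+eXY=0\n")
    with pytest.raises(tx.TaxonomyError, match="unsatisfiable"):
        tx.load_taxonomy(path)


def test_duplicate_solution_sets_rejected_at_load(tmp_path):
    path = tmp_path / "dup.tsv"
    rel = "+e0-eXY<0 ; +e0-eX=0 ; +eX-eY=0 ; +e0-eX-eY+eXY>0"
    path.write_text(f"1\ta\temergent\t+\tboth\t{rel}\n"
                    f"2\tb\temergent\t+\tboth\t{rel}\n")
    with pytest.raises(tx.TaxonomyError, match="not distinguishable"):
        tx.load_taxonomy(path)


def test_duplicate_ids_rejected(tmp_path):
    path = tmp_path / "dupid.tsv"
    rel = "+e0-eXY<0 ; +e0-eX=0 ; +eX-eY=0 ; +e0-eX-eY+eXY>0"
    path.write_text(f"7\ta\temergent\t+\tboth\t{rel}\n"
                    f"7\tb\temergent\t+\tboth\t{rel}\n")
    with pytest.raises(tx.TaxonomyError, match="duplicate profile id"):
        tx.load_taxonomy(path)


def test_relation_string_round_trip():
    rel = tx.LinearRelation.from_string("+e0-eX-eY+eXY>0")
    assert rel.to_string() == "+e0-eX-eY+eXY>0"
    rel2 = tx.LinearRelation.from_string("-2*e0+eX+eY<0")
    assert rel2.coeffs[0] == -2
    assert rel2.to_string() == "-2*e0+eX+eY<0"


def test_match_tolerance_snaps_near_ties(taxonomy):
    # a 0.001 wobble below the tolerance is treated as no single-agent
    # effect: the vector matches the emergent-synergy profile
    assert taxonomy.match((0, 0.001, 0, 5), tolerance=0.01) == 3
    assert taxonomy.match((0, 0, 0, 0)) == 1
    assert taxonomy.match((0, 0, 0, 5)) == 3


def test_partition_of_random_vectors(taxonomy):
    """Every random mean vector matches exactly one profile: the matched
    system is satisfied and all other systems are violated."""
    rng = np.random.default_rng(42)
    vectors = rng.uniform(-14, 14, size=(10_000, 4))
    ids = np.array([taxonomy.match(v) for v in vectors])
    assert set(ids) <= set(taxonomy.ids)
    # spot-check exclusivity on a subsample against the relation systems
    for v, pid in zip(vectors[:200], ids[:200]):
        assert taxonomy[pid].satisfies(v, 1e-12)
        others = [q.id for q in taxonomy.profiles
                  if q.id != pid and q.satisfies(v, 1e-12)]
        assert others == []


@settings(max_examples=200, deadline=None)
@given(st.tuples(*[st.floats(-14, 14, allow_nan=False) for _ in range(4)]))
def test_match_is_total_on_admissible_vectors(v):
    tax = tx.default_taxonomy()
    pid = tax.match(v)
    assert 1 <= pid <= 123


def test_mirror_swaps_stimulus_roles(taxonomy):
    """X<->Y relabeling is an involution and preserves category and sign."""
    for p in taxonomy.profiles:
        mid = taxonomy.mirror_id(p.id)
        assert taxonomy.mirror_id(mid) == p.id
        assert taxonomy.category_of(mid) == p.category
        assert taxonomy.interaction_sign_of(mid) == p.interaction_sign
        swapped = {"X": "Y", "Y": "X"}.get(p.target, p.target)
        assert taxonomy[mid].target == swapped


def test_bliss_index_examples():
    assert tx.bliss_index((2.2, 2.2, 2.2, 5.5)) == pytest.approx(3.3)
    assert tx.bliss_index((0, 1, 2, 3)) == pytest.approx(0.0)
    assert tx.bliss_index((0, 1, 2, 4)) == pytest.approx(1.0)
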
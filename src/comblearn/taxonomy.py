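"""Taxonomy of interaction profiles for four-condition combination-treatment designs.

A combination-treatment experiment measures a response under a vehicle control
(0), two single stimuli (X, Y) and their combination (X+Y).  A qualitative
response pattern -- an *interaction profile* -- is a satisfiable system of
sign relations over the four condition means ``(e0, eX, eY, eXY)``.

The complete taxonomy contains 123 distinguishable profiles.  They arise as
the weak orders (ordered set partitions) of the five values

    e0, eX, eY, eXY,  eAdd = eX + eY - e0

that are feasible under the affine dependence of the additive prediction
``eAdd`` on the other three (123 of the 541 candidate weak orders on five
elements survive the feasibility filter; verified by linear programming).
The position of the combination relative to the additive prediction encodes
the Bliss interaction sign: ``eXY > eAdd`` is synergistic, ``eXY < eAdd``
antagonistic, ``eXY = eAdd`` additive.

The taxonomy ships as a declarative, human-auditable definition file
(``data/taxonomy.tsv``), which is the source of truth at run time.  The
enumerator :func:`enumerate_profiles` regenerates the same content from first
principles and serves as a cross-check, not as the runtime source.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog

#: free variable basis, fixed order
VARIABLES = ("e0", "eX", "eY", "eXY")

#: the five ordered values: the four condition means plus the additive
#: prediction, each as a row of coefficients over the basis
VALUE_SYMBOLS = ("e0", "eX", "eY", "eXY", "eAdd")
_VALUE_ROWS = (
    (Fraction(1), Fraction(0), Fraction(0), Fraction(0)),
    (Fraction(0), Fraction(1), Fraction(0), Fraction(0)),
    (Fraction(0), Fraction(0), Fraction(1), Fraction(0)),
    (Fraction(0), Fraction(0), Fraction(0), Fraction(1)),
    (Fraction(-1), Fraction(1), Fraction(1), Fraction(0)),
)

#: coefficients of the Bliss term B = eXY - eAdd = e0 - eX - eY + eXY
BLISS_COEFFS = (Fraction(1), Fraction(-1), Fraction(-1), Fraction(1))

#: admissible log2 expression range
DEFAULT_RANGE = (-14.0, 14.0)

CATEGORIES = (
    "constant",
    "emergent",
    "additive",
    "potentiation",
    "inhibition",
    "suppression",
    "restoration",
    "ceiling",
    "floor",
    "synergistic_reversal",
    "antagonistic_reversal",
)

TAXONOMY_VERSION = "1.0"

#: pinned checksum of the packaged definition file
TAXONOMY_SHA256 = "a45ebf89fdc275516484b358c7a29d7be1858c3d2a0c2fa53c88391e5c235906"


class TaxonomyError(ValueError):
    """Raised when a taxonomy definition fails validation."""


@dataclass(frozen=True)
class LinearRelation:
    """A sign relation ``coeffs . (e0, eX, eY, eXY)  op  0``.

    Coefficients are exact rationals so that definitions carry no float
    drift; ``op`` is one of ``'<'``, ``'='``, ``'>'``.
    """

    coeffs: tuple[Fraction, Fraction, Fraction, Fraction]
    op: str

    def __post_init__(self):
        if self.op not in ("<", "=", ">"):
            raise TaxonomyError(f"invalid relation operator {self.op!r}")
        if all(c == 0 for c in self.coeffs):
            raise TaxonomyError("relation has a zero coefficient vector")

    def evaluate(self, v: Sequence[float]) -> float:
        return float(sum(float(c) * float(x) for c, x in zip(self.coeffs, v)))

    def holds(self, v: Sequence[float], tolerance: float = 0.0) -> bool:
        """True iff the relation holds at ``v``.

        ``|expression| <= tolerance`` counts as equality; strict relations
        require a margin greater than ``tolerance``.
        """
        x = self.evaluate(v)
        if self.op == "=":
            return abs(x) <= tolerance
        if self.op == "<":
            return x < -tolerance
        return x > tolerance

    def to_string(self) -> str:
        parts = []
        for c, name in zip(self.coeffs, VARIABLES):
            if c == 0:
                continue
            if c == 1:
                parts.append(f"+{name}")
            elif c == -1:
                parts.append(f"-{name}")
            else:
                sign = "+" if c > 0 else "-"
                parts.append(f"{sign}{abs(c)}*{name}")
        return "".join(parts) + self.op + "0"

    @classmethod
    def from_string(cls, text: str) -> "LinearRelation":
        text = text.strip().replace(" ", "")
        for op in ("<", "=", ">"):
            if op in text:
                lhs, rhs = text.split(op, 1)
                break
        else:
            raise TaxonomyError(f"relation {text!r} has no operator")
        if rhs != "0":
            raise TaxonomyError(f"relation {text!r} must compare against 0")
        coeffs = [Fraction(0)] * 4
        i = 0
        if lhs and lhs[0] not in "+-":
            lhs = "+" + lhs
        while i < len(lhs):
            sign = 1 if lhs[i] == "+" else -1
            i += 1
            j = i
            while j < len(lhs) and lhs[j] not in "+-":
                j += 1
            term = lhs[i:j]
            if "*" in term:
                mag, name = term.split("*", 1)
                coeff = Fraction(mag)
            else:
                coeff, name = Fraction(1), term
            if name not in VARIABLES:
                raise TaxonomyError(f"unknown variable {name!r} in {text!r}")
            coeffs[VARIABLES.index(name)] += sign * coeff
            i = j
        return cls(tuple(coeffs), op)


@dataclass(frozen=True)
class InteractionProfile:
    """One taxonomy entry: a satisfiable system of sign relations.

    ``interaction_sign`` is the sign of the Bliss term on the profile's
    solution set (+1 synergistic, -1 antagonistic, 0 non-interacting).
    ``target`` records whose single-stimulus effect the combination
    qualitatively alters ('X', 'Y', 'both' or 'none'); it drives the
    context-dependence slicing of the landscape.
    """

    id: int
    name: str
    category: str
    interaction_sign: int
    relations: tuple[LinearRelation, ...]
    target: str = "none"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise TaxonomyError(f"unknown category {self.category!r}")
        if self.interaction_sign not in (-1, 0, 1):
            raise TaxonomyError("interaction_sign must be -1, 0 or +1")
        if self.target not in ("X", "Y", "both", "none"):
            raise TaxonomyError(f"invalid target {self.target!r}")
        if not self.relations:
            raise TaxonomyError(f"profile {self.id} has no relations")
        consistent = (self.category in ("constant", "additive")) == \
            (self.interaction_sign == 0)
        if not consistent:
            raise TaxonomyError(
                f"profile {self.id}: category {self.category!r} is "
                f"inconsistent with interaction sign {self.interaction_sign}")

    def satisfies(self, v: Sequence[float], tolerance: float = 0.0) -> bool:
        return all(r.holds(v, tolerance) for r in self.relations)


def satisfies(profile: InteractionProfile, v: Sequence[float],
              tolerance: float = 0.0) -> bool:
    """True iff ``v`` satisfies every relation of ``profile``.

    ``|expression| <= tolerance`` counts as equality; strict relations
    require margin > tolerance.  Total function for finite input.
    """
    return profile.satisfies(v, tolerance)


def bliss_index(v: Sequence[float]) -> float:
    """Average Bliss index b = (eXY - e0) - ((eX - e0) + (eY - e0)).

    Positive for synergistic, negative for antagonistic deviations from
    additivity; invariant under adding a constant to all four means.
    """
    e0, eX, eY, eXY = (float(x) for x in v)
    return (eXY - e0) - ((eX - e0) + (eY - e0))


def five_values(v: Sequence[float]) -> np.ndarray:
    """The four condition means extended with the additive prediction."""
    v = np.asarray(v, dtype=float)
    return np.append(v, v[1] + v[2] - v[0])


# ---------------------------------------------------------------------------
# enumeration of the canonical taxonomy


def _weak_orders(n: int) -> list[tuple[int, ...]]:
    """All weak orders on n labeled elements as contiguous rank patterns."""
    seen: set[tuple[int, ...]] = set()
    out = []
    for ranks in product(range(n), repeat=n):
        levels = sorted(set(ranks))
        norm = tuple(levels.index(r) for r in ranks)
        if norm not in seen:
            seen.add(norm)
            out.append(norm)
    return out


def _relations_for(pattern: tuple[int, ...]) -> tuple[LinearRelation, ...]:
    """Relation system characterizing a weak order of the five values.

    Equalities chain the members of each rank group; one strict inequality
    links each pair of consecutive groups (transitivity supplies the rest).
    Relations are expressed over the free basis (e0, eX, eY, eXY) by
    substituting eAdd = eX + eY - e0.
    """
    k = max(pattern) + 1
    groups = [[i for i in range(5) if pattern[i] == lev] for lev in range(k)]
    rels: list[LinearRelation] = []

    def row(i):
        return _VALUE_ROWS[i]

    for members in groups:
        for a, b in zip(members, members[1:]):
            coeffs = tuple(ca - cb for ca, cb in zip(row(a), row(b)))
            rels.append(LinearRelation(coeffs, "="))
    for lo, hi in zip(groups, groups[1:]):
        coeffs = tuple(ca - cb for ca, cb in zip(row(lo[0]), row(hi[0])))
        rels.append(LinearRelation(coeffs, "<"))
    return tuple(rels)


def _bliss_sign_of_pattern(pattern: tuple[int, ...]) -> int:
    return (pattern[3] > pattern[4]) - (pattern[3] < pattern[4])


def _order_string(pattern: tuple[int, ...]) -> str:
    symbols = ("0", "X", "Y", "XY", "A")
    k = max(pattern) + 1
    groups = ["=".join(symbols[i] for i in range(5) if pattern[i] == lev)
              for lev in range(k)]
    return "<".join(groups)


def _sign_char(s: int) -> str:
    return {1: "+", -1: "-", 0: "0"}[s]


def _categorize(pattern: tuple[int, ...]) -> tuple[str, str, str]:
    """Assign (category, label, target) to a feasible five-value weak order.

    dX, dY, dXY are the signs of the single-stimulus and combination effects
    relative to control; s is the Bliss sign.  The rules follow the
    qualitative vocabulary of the field: emergence (effect only in the
    combination), potentiation (amplification of an existing effect),
    inhibition (partial reduction), suppression/restoration (complete
    cancellation of an up-/down-effect), floor/ceiling (saturation at the
    extreme single-effect level) and synergistic/antagonistic reversals.
    """
    r0, rX, rY, rXY, _ = pattern
    s = _bliss_sign_of_pattern(pattern)
    dX = (rX > r0) - (rX < r0)
    dY = (rY > r0) - (rY < r0)
    dXY = (rXY > r0) - (rXY < r0)

    if r0 == rX == rY == rXY:
        return "constant", "constant response", "none"
    if s == 0:
        return "additive", "additive (no interaction)", "none"
    if dX == 0 and dY == 0:
        label = "emergent synergy" if s > 0 else "emergent antagonism"
        return "emergent", label, "both"

    if (dX == 0) != (dY == 0):
        # exactly one stimulus has a single-agent effect
        active, partner = ("X", "Y") if dX != 0 else ("Y", "X")
        a = dX if dX != 0 else dY
        rA = rX if dX != 0 else rY
        if dXY == 0:
            if a > 0:
                return "suppression", f"{partner} suppresses {active}", active
            return "restoration", f"{partner} restores {active}", active
        if dXY == -a:
            cat = "synergistic_reversal" if s > 0 else "antagonistic_reversal"
            return cat, f"{partner} reverses {active}", active
        beyond = rXY > rA if a > 0 else rXY < rA
        if beyond:
            return "potentiation", f"{partner} potentiates {active}", active
        return "inhibition", f"{partner} inhibits {active}", active

    if dX == dY:
        # both stimuli push the same way
        a = dX
        hi = max(rX, rY) if a > 0 else min(rX, rY)
        if dXY == 0:
            if a > 0:
                return "suppression", "mutual suppression", "both"
            return "restoration", "mutual restoration", "both"
        if dXY == -a:
            cat = "synergistic_reversal" if s > 0 else "antagonistic_reversal"
            return cat, "combination reverses X and Y", "both"
        if (a > 0 and rXY > hi) or (a < 0 and rXY < hi):
            if s == a:
                return "potentiation", "X and Y potentiate each other", "both"
            return (("ceiling", "sub-additive ceiling", "both") if a > 0
                    else ("floor", "sub-additive floor", "both"))
        if rXY == hi:
            return (("ceiling", "ceiling at strongest effect", "both") if a > 0
                    else ("floor", "floor at strongest effect", "both"))
        return "inhibition", "mutual inhibition", "both"

    # opposite single-agent effects
    up, dn = ("X", "Y") if dX > 0 else ("Y", "X")
    r_up = rX if dX > 0 else rY
    r_dn = rY if dX > 0 else rX
    if dXY == 0:
        return "suppression", f"{up} and {dn} cancel", "both"
    if dXY > 0:
        if rXY == r_up:
            return "suppression", f"{up} suppresses {dn}", dn
        if rXY > r_up:
            return "potentiation", f"{up} potentiated despite {dn}", "both"
        return "inhibition", f"{dn} inhibits {up}", up
    if rXY == r_dn:
        return "suppression", f"{dn} suppresses {up}", up
    if rXY < r_dn:
        return "potentiation", f"{dn} enhanced despite {up}", "both"
    return "inhibition", f"{up} inhibits {dn}", dn


def enumerate_profiles() -> list[InteractionProfile]:
    """Enumerate the canonical 123-profile taxonomy from first principles.

    Cross-check tool for the packaged definition file: all weak orders of
    (e0, eX, eY, eXY, eAdd) are generated and filtered for affine
    feasibility by LP.  Ids are assigned by category block (constant first,
    then emergent, so that 'emergent synergy' is profile 3) and, within a
    block, by (#distinct levels, Bliss sign, rank pattern).
    """
    cells = []
    for pattern in _weak_orders(5):
        rels = _relations_for(pattern)
        if interior_point(rels) is None:
            continue
        category, label, target = _categorize(pattern)
        cells.append((pattern, category, label, target, rels))
    order_key = {c: i for i, c in enumerate(CATEGORIES)}
    cells.sort(key=lambda c: (order_key[c[1]], max(c[0]) + 1,
                              _bliss_sign_of_pattern(c[0]), c[0]))
    profiles = []
    for pid, (pattern, category, label, target, rels) in enumerate(cells, 1):
        s = _bliss_sign_of_pattern(pattern)
        name = f"{label} [{_order_string(pattern)}]"
        profiles.append(InteractionProfile(
            id=pid, name=name, category=category, interaction_sign=s,
            relations=rels, target=target))
    return profiles


# ---------------------------------------------------------------------------
# feasibility / interior points


def interior_point(relations: Iterable[LinearRelation],
                   admissible_range: tuple[float, float] = DEFAULT_RANGE,
                   ) -> np.ndarray | None:
    """A strictly feasible point of a relation system, or None.

    Solves an LP maximizing the common margin m of the strict relations
    subject to the equalities and the admissible box; strict feasibility
    means max m > 0.
    """
    lo, hi = admissible_range
    A_ub, b_ub, A_eq, b_eq = [], [], [], []
    for r in relations:
        row = [float(c) for c in r.coeffs]
        if r.op == "=":
            A_eq.append(row + [0.0])
            b_eq.append(0.0)
        elif r.op == ">":
            A_ub.append([-c for c in row] + [1.0])
            b_ub.append(0.0)
        else:
            A_ub.append(row + [1.0])
            b_ub.append(0.0)
    c = [0.0] * 4 + [-1.0]
    bounds = [(lo, hi)] * 4 + [(0.0, 1.0)]
    res = linprog(c, A_ub=A_ub or None, b_ub=b_ub or None,
                  A_eq=A_eq or None, b_eq=b_eq or None,
                  bounds=bounds, method="highs")
    if not res.success or res.x[4] <= 1e-9:
        return None
    return res.x[:4]


# ---------------------------------------------------------------------------
# Taxonomy container


@dataclass
class Taxonomy:
    """The loaded profile collection plus the matching tolerance."""

    profiles: list[InteractionProfile]
    tolerance: float = 0.0
    version: str = TAXONOMY_VERSION
    _by_id: dict[int, InteractionProfile] = field(default_factory=dict,
                                                  repr=False)
    _witness: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _by_pattern: dict[tuple[int, ...], int] = field(default_factory=dict,
                                                    repr=False)

    def __post_init__(self):
        if self.tolerance < 0:
            raise TaxonomyError("tolerance must be >= 0")
        self._by_id = {p.id: p for p in self.profiles}

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, pid: int) -> InteractionProfile:
        try:
            return self._by_id[int(pid)]
        except KeyError:
            raise KeyError(f"unknown profile id {pid}") from None

    @property
    def ids(self) -> list[int]:
        return sorted(self._by_id)

    def category_of(self, pid: int) -> str:
        return self[pid].category

    def interaction_sign_of(self, pid: int) -> int:
        return self[pid].interaction_sign

    def profiles_in_category(self, category: str) -> list[InteractionProfile]:
        if category not in CATEGORIES:
            raise TaxonomyError(f"unknown category {category!r}")
        return [p for p in self.profiles if p.category == category]

    def witness(self, pid: int) -> np.ndarray:
        """A strictly feasible mean vector of the profile."""
        w = self._witness.get(pid)
        if w is None:
            w = interior_point(self[pid].relations)
            if w is None:
                raise TaxonomyError(f"profile {pid}: unsatisfiable system")
            self._witness[pid] = w
        return w

    # -- matching -----------------------------------------------------------

    def canonicalize(self, v: Sequence[float],
                     tolerance: float | None = None) -> np.ndarray:
        """Snap near-ties among the four means (|diff| <= tolerance,
        transitively closed) to exact equality via the group mean."""
        tol = self.tolerance if tolerance is None else tolerance
        v = np.asarray(v, dtype=float)
        groups = _tie_groups(v, tol)
        out = v.copy()
        for members in groups:
            out[members] = v[members].mean()
        return out

    def _pattern_index(self) -> dict[tuple[int, ...], int]:
        if not self._by_pattern:
            for p in self.profiles:
                pat = _pattern_of(five_values(self.witness(p.id)), 1e-7)
                self._by_pattern[pat] = p.id
        return self._by_pattern

    def match(self, v: Sequence[float],
              tolerance: float | None = None) -> int:
        """Deterministically assign a mean vector to its profile.

        The vector is canonicalized (near-ties snapped to equality), the
        additive prediction appended, and the resulting five-value rank
        pattern looked up.  A tolerance-snapped pattern that is infeasible
        (possible only for adversarial tie chains) falls back to the exact
        pattern of the canonical vector, which is always realizable.  If the
        taxonomy is not the complete partition, matching falls back to a
        relation scan; ties resolve to the lowest id with a warning.
        """
        tol = self.tolerance if tolerance is None else tolerance
        w = self.canonicalize(v, tol)
        v5 = five_values(w)
        index = self._pattern_index()
        for t in (tol, 0.0):
            pid = index.get(_pattern_of(v5, t))
            if pid is not None:
                return pid
        hits = [p.id for p in self.profiles if p.satisfies(w, 1e-9)]
        if not hits:
            raise TaxonomyError(f"no profile matches vector {list(v)}")
        if len(hits) > 1:
            warnings.warn(f"vector {list(v)} matches profiles {hits}; "
                          "returning the lowest id", stacklevel=2)
        return min(hits)

    def mirror_id(self, pid: int) -> int:
        """Id of the profile obtained by swapping the roles of X and Y."""
        w = self.witness(pid)
        return self.match([w[0], w[2], w[1], w[3]], tolerance=1e-9)


def _tie_groups(values: np.ndarray, tol: float) -> list[np.ndarray]:
    """Transitive closure of |v_i - v_j| <= tol as index groups."""
    n = len(values)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(values[i] - values[j]) <= tol:
                parent[find(i)] = find(j)
    roots = sorted(set(find(i) for i in range(n)))
    return [np.array([i for i in range(n) if find(i) == r]) for r in roots]


def _pattern_of(v5: np.ndarray, tol: float) -> tuple[int, ...]:
    """Contiguous rank pattern of the five values with tie tolerance."""
    groups = _tie_groups(v5, tol)
    groups.sort(key=lambda g: v5[g].mean())
    pattern = [0] * 5
    for rank, members in enumerate(groups):
        for i in members:
            pattern[i] = rank
    return tuple(pattern)


def match_deterministic(v: Sequence[float], taxonomy: Taxonomy,
                        tolerance: float | None = None) -> int:
    """Functional form of :meth:`Taxonomy.match`."""
    return taxonomy.match(v, tolerance)


# ---------------------------------------------------------------------------
# serialization


_HEADER = ["id", "name", "category", "sign", "target", "relations"]


def write_taxonomy(profiles: Sequence[InteractionProfile], path: Path | str,
                   version: str = TAXONOMY_VERSION) -> None:
    lines = [f"# interaction-profile taxonomy v{version}",
             "# columns: " + "\t".join(_HEADER)]
    for p in profiles:
        rels = " ; ".join(r.to_string() for r in p.relations)
        lines.append("\t".join([
            str(p.id), p.name, p.category, _sign_char(p.interaction_sign),
            p.target, rels]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_taxonomy(definition_file: Path | str, tolerance: float = 0.0,
                  validate: bool = True) -> Taxonomy:
    """Load a taxonomy definition file and validate its invariants.

    Validation checks, per profile, LP feasibility of the relation system
    inside the admissible range (an unsatisfiable system is a load failure
    naming the profile) and pairwise distinguishability via interior-point
    certificates: the strictly feasible witness of each profile must violate
    every other profile's system.
    """
    path = Path(definition_file)
    text = path.read_text(encoding="utf-8")
    version = TAXONOMY_VERSION
    profiles: list[InteractionProfile] = []
    seen_ids: set[int] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            if line.startswith("# interaction-profile taxonomy v"):
                version = line.rsplit("v", 1)[1].strip()
            continue
        fields = line.split("\t")
        if len(fields) != len(_HEADER):
            raise TaxonomyError(f"line {lineno}: expected {len(_HEADER)} "
                                f"fields, got {len(fields)}")
        pid = int(fields[0])
        if pid in seen_ids:
            raise TaxonomyError(f"duplicate profile id {pid}")
        seen_ids.add(pid)
        sign = {"+": 1, "-": -1, "0": 0}.get(fields[3])
        if sign is None:
            raise TaxonomyError(f"line {lineno}: invalid sign {fields[3]!r}")
        relations = tuple(LinearRelation.from_string(r)
                          for r in fields[5].split(";") if r.strip())
        profiles.append(InteractionProfile(
            id=pid, name=fields[1], category=fields[2],
            interaction_sign=sign, relations=relations, target=fields[4]))
    if not profiles:
        raise TaxonomyError(f"{path}: no profiles found")
    tax = Taxonomy(profiles, tolerance=tolerance, version=version)
    if validate:
        _validate(tax)
    return tax


def _validate(tax: Taxonomy) -> None:
    for p in tax.profiles:
        w = interior_point(p.relations)
        if w is None:
            raise TaxonomyError(f"profile {p.id} ({p.name}): "
                                "unsatisfiable relation system")
        tax._witness[p.id] = w
    for p in tax.profiles:
        w = tax._witness[p.id]
        for q in tax.profiles:
            if q.id != p.id and q.satisfies(w, 1e-9):
                raise TaxonomyError(
                    f"profiles {p.id} and {q.id} are not distinguishable: "
                    f"witness of {p.id} also satisfies {q.id}")


def packaged_taxonomy_path() -> Path:
    return Path(resources.files("comblearn.data") / "taxonomy.tsv")


@lru_cache(maxsize=None)
def default_taxonomy(tolerance: float = 0.0) -> Taxonomy:
    """The packaged 123-profile taxonomy (checksum-verified, validated)."""
    path = packaged_taxonomy_path()
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != TAXONOMY_SHA256:
        raise TaxonomyError("packaged taxonomy checksum mismatch")
    tax = load_taxonomy(path, tolerance=tolerance)
    if len(tax) != 123:
        raise TaxonomyError(f"packaged taxonomy has {len(tax)} profiles, "
                            "expected 123")
    return tax
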
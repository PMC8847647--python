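"""Switch analysis: presence binarisation and U/A/B classification.

For each phenotype group and tissue compartment, a lipid variable's
presence fraction ``B`` is the proportion of that group's samples in that
compartment with signal strength > 0.  The variable is *present* in the
cell when ``B >= threshold`` (default 0.66, a closed bound, so exactly
66/100 counts).  The comparison is done in exact rational arithmetic so
that e.g. 6 of 8 samples (3/4) is unambiguously above 33/50.

On the compartment network, each group's presence pattern classifies every
variable as

* **U-type** — present in exactly one compartment (unique),
* **A-type** — present in every compartment (ubiquitous),
* **B-type** on an edge — present in both endpoint compartments of that
  adjacent pair.  B-lists are per-edge and non-exclusive, so the A-list is
  a subset of every B-list.

The two groups are classified fully independently; their lists are then
aligned into equal-length binary vectors over the union of variables in a
given scope for the overlap statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .nomenclature import LipidSpecies, sort_key
from .io import LipidomicsDataset
from .network import TissueNetwork, edge_key

__all__ = [
    "DEFAULT_THRESHOLD",
    "presence_fraction",
    "PresenceProfile",
    "binarize",
    "VariableRecord",
    "SwitchClassification",
    "classify_switch",
    "Scope",
    "AlignedLists",
    "align_binary_lists",
    "classification_table",
]

DEFAULT_THRESHOLD = Fraction(66, 100)


def as_fraction(threshold: float | str | Fraction) -> Fraction:
    """Convert a threshold to an exact rational via its decimal spelling."""
    if isinstance(threshold, Fraction):
        return threshold
    return Fraction(str(threshold))


def presence_fraction(values: Sequence[float] | np.ndarray) -> Fraction:
    """Exact proportion of entries with signal strength > 0.

    >>> presence_fraction([1.2, 0, 3.4, 5.0])
    Fraction(3, 4)
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("presence_fraction needs a non-empty sequence")
    if (arr < 0).any():
        raise ValueError("signal strengths must be non-negative")
    return Fraction(int((arr > 0).sum()), int(arr.size))


@dataclass
class PresenceProfile:
    """Per (group, compartment, variable) detection counts and presence calls.

    ``counts`` is a DataFrame indexed by (group, compartment) with one
    column per variable holding the number of samples with signal > 0;
    ``n_samples`` gives each cell's sample count.  Presence is decided
    exactly: ``count / n >= threshold`` as rationals.
    """

    counts: pd.DataFrame
    n_samples: pd.Series
    threshold: Fraction
    variables: list[LipidSpecies]

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted({g for g, _ in self.counts.index}))

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(sorted({c for _, c in self.counts.index}))

    @property
    def b_fraction(self) -> pd.DataFrame:
        """Presence fractions as floats (for display; calls use exact math)."""
        return self.counts.div(self.n_samples, axis=0)

    @property
    def present(self) -> pd.DataFrame:
        """Boolean presence calls, exact at the threshold boundary."""
        # count/n >= p/q  <=>  count * q >= p * n   (all non-negative ints)
        p, q = self.threshold.numerator, self.threshold.denominator
        n = self.n_samples.to_numpy()[:, None]
        return pd.DataFrame(
            self.counts.to_numpy() * q >= p * n,
            index=self.counts.index,
            columns=self.counts.columns,
        )

    def present_set(self, group: str, compartment: str) -> frozenset[str]:
        row = self.present.loc[(group, compartment)]
        return frozenset(row.index[row])


def binarize(
    dataset: LipidomicsDataset,
    threshold: float | str | Fraction = DEFAULT_THRESHOLD,
) -> PresenceProfile:
    """Compute the complete presence profile of a dataset.

    Every (group, compartment) cell must contain at least one sample;
    empty cells are reported by name.
    """
    thr = as_fraction(threshold)
    if not 0 <= thr <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {thr}")
    groups = sorted(dataset.samples["group"].unique())
    compartments = sorted(dataset.samples["compartment"].unique())
    detected = dataset.abundance.to_numpy() > 0

    rows, ns, index = [], [], []
    for g in groups:
        for c in compartments:
            mask = (
                (dataset.samples["group"] == g)
                & (dataset.samples["compartment"] == c)
            ).to_numpy()
            n = int(mask.sum())
            if n == 0:
                raise ValueError(
                    f"no samples in group {g!r}, compartment {c!r}: "
                    "every group x compartment cell needs at least 1 sample"
                )
            rows.append(detected[mask].sum(axis=0))
            ns.append(n)
            index.append((g, c))
    midx = pd.MultiIndex.from_tuples(index, names=["group", "compartment"])
    counts = pd.DataFrame(
        np.asarray(rows, dtype=int), index=midx, columns=dataset.abundance.columns
    )
    return PresenceProfile(
        counts=counts,
        n_samples=pd.Series(ns, index=midx, name="n"),
        threshold=thr,
        variables=list(dataset.variables),
    )


@dataclass(frozen=True)
class VariableRecord:
    """Traceability record for one variable in one group."""

    variable: str
    group: str
    present_compartments: frozenset[str]
    category: str  # "absent" | "U@<comp>" | "A" | "shared" | "shared-nonadjacent"


@dataclass
class SwitchClassification:
    """One group's U/A/B structures over the network.

    ``u_lists`` maps each compartment to the variables present only there;
    ``a_list`` holds variables present everywhere; ``b_lists`` maps each
    network edge to the variables present in both endpoints (non-exclusive,
    so ``a_list`` is a subset of every B-list).  Variables detected nowhere
    are kept in ``not_detected``.
    """

    group: str
    network: TissueNetwork
    u_lists: dict[str, set[str]]
    a_list: set[str]
    b_lists: dict[tuple[str, str], set[str]]
    not_detected: set[str]
    records: dict[str, VariableRecord] = field(default_factory=dict)


def _classify_group(
    group: str, profile: PresenceProfile, network: TissueNetwork
) -> SwitchClassification:
    comps = network.compartments
    present = {c: profile.present_set(group, c) for c in comps}
    u_lists: dict[str, set[str]] = {c: set() for c in comps}
    a_list: set[str] = set()
    b_lists: dict[tuple[str, str], set[str]] = {
        edge_key(*e): set(present[e[0]] & present[e[1]]) for e in network.edges
    }
    not_detected: set[str] = set()
    records: dict[str, VariableRecord] = {}
    adjacency = {edge_key(*e) for e in network.edges}

    for var in profile.counts.columns:
        where = frozenset(c for c in comps if var in present[c])
        if not where:
            category = "absent"
            not_detected.add(var)
        elif len(where) == 1:
            (only,) = where
            category = f"U@{only}"
            u_lists[only].add(var)
        elif len(where) == len(comps):
            category = "A"
            a_list.add(var)
        else:
            on_edge = any(
                edge_key(a, b) in adjacency
                for a in where for b in where if a < b
            )
            category = "shared" if on_edge else "shared-nonadjacent"
        records[var] = VariableRecord(
            variable=var, group=group, present_compartments=where, category=category
        )
    return SwitchClassification(
        group=group,
        network=network,
        u_lists=u_lists,
        a_list=a_list,
        b_lists=b_lists,
        not_detected=not_detected,
        records=records,
    )


def classify_switch(
    profile: PresenceProfile, network: TissueNetwork
) -> dict[str, SwitchClassification]:
    """Classify every variable as U/A/B for each group independently."""
    missing = set(network.compartments) - set(profile.compartments)
    if missing:
        raise ValueError(
            f"profile lacks network compartments: {sorted(missing)}"
        )
    extra = set(profile.compartments) - set(network.compartments)
    if extra:
        raise ValueError(
            f"profile has compartments not in the network: {sorted(extra)}"
        )
    return {g: _classify_group(g, profile, network) for g in profile.groups}


@dataclass(frozen=True)
class Scope:
    """Selects one category of variables at one network location.

    ``category`` is "U" (requires a compartment), "A" (no location) or "B"
    (requires an edge); ``lipid_class`` optionally restricts to one class.
    """

    category: str
    compartment: str | None = None
    edge: tuple[str, str] | None = None
    lipid_class: str | None = None

    def label(self) -> str:
        loc = ""
        if self.category == "U":
            loc = f"@{self.compartment}"
        elif self.category == "B":
            loc = "@{}-{}".format(*self.edge)  # type: ignore[misc]
        cls = f" {self.lipid_class}" if self.lipid_class else ""
        return f"{self.category}-type{cls}{loc}"


def _scope_members(cls: SwitchClassification, scope: Scope,
                   species: Mapping[str, LipidSpecies]) -> set[str]:
    if scope.category == "U":
        if scope.compartment is None:
            raise ValueError("U scope needs a compartment")
        members = set(cls.u_lists[scope.compartment])
    elif scope.category == "A":
        members = set(cls.a_list)
    elif scope.category == "B":
        if scope.edge is None:
            raise ValueError("B scope needs an edge")
        members = set(cls.b_lists[edge_key(*scope.edge)])
    else:
        raise ValueError(f"unknown scope category {scope.category!r}")
    if scope.lipid_class is not None:
        members = {m for m in members if species[m].lipid_class == scope.lipid_class}
    return members


@dataclass
class AlignedLists:
    """Equal-length binary membership vectors over a sorted variable union."""

    names: list[str]
    vector_g1: np.ndarray
    vector_g2: np.ndarray
    group_g1: str
    group_g2: str
    scope: Scope


def align_binary_lists(
    class_g1: SwitchClassification,
    class_g2: SwitchClassification,
    scope: Scope,
    species: Mapping[str, LipidSpecies] | Iterable[LipidSpecies],
) -> AlignedLists:
    """Align two groups' in-scope variable lists into binary vectors.

    The union of both groups' members is placed in canonical order (lipid
    class, carbons, double bonds, raw name); each group contributes a 0/1
    membership vector.  An empty union is an error — there is nothing to
    compare.
    """
    if class_g1.network != class_g2.network:
        raise ValueError("classifications were built on different networks")
    if not isinstance(species, Mapping):
        species = {s.raw_name: s for s in species}
    s1 = _scope_members(class_g1, scope, species)
    s2 = _scope_members(class_g2, scope, species)
    union = s1 | s2
    if not union:
        raise ValueError(f"nothing to compare in scope {scope.label()}")
    names = sorted(union, key=lambda n: sort_key(species[n]))
    v1 = np.array([int(n in s1) for n in names], dtype=int)
    v2 = np.array([int(n in s2) for n in names], dtype=int)
    return AlignedLists(
        names=names, vector_g1=v1, vector_g2=v2,
        group_g1=class_g1.group, group_g2=class_g2.group, scope=scope,
    )


def classification_table(
    classifications: Mapping[str, SwitchClassification]
) -> pd.DataFrame:
    """Long-format table of every (group, variable) record."""
    rows = []
    for g in sorted(classifications):
        for rec in classifications[g].records.values():
            rows.append(
                {
                    "group": g,
                    "variable": rec.variable,
                    "category": rec.category,
                    "n_compartments": len(rec.present_compartments),
                    "compartments": ";".join(sorted(rec.present_compartments)),
                }
            )
    return pd.DataFrame(rows, columns=[
        "group", "variable", "category", "n_compartments", "compartments"
    ])
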
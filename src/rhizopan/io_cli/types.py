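"""Core domain types shared by every analysis stage.

The whole pipeline operates on three kinds of objects: ortholog cluster
sets (genome, gene) membership lists, binary strain x feature presence
matrices, and a strain -> isolation-compartment label map.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ConsistencyError

RHIZOSPHERE = "rhizosphere"
ENDOSPHERE = "endosphere"
COMPARTMENTS = (RHIZOSPHERE, ENDOSPHERE)

#: Recognised matrix kinds. ``presence`` is a gene-cluster (or reaction)
#: occupancy matrix; the others are phenotype-style tables.
MATRIX_KINDS = ("trait", "utilization", "prediction", "presence")


@dataclass(frozen=True)
class Cluster:
    """One ortholog cluster: an id plus its (genome_id, gene_id) members."""

    id: str
    members: frozenset[tuple[str, str]]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"cluster {self.id!r} has no members")

    @property
    def genomes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.members)


@dataclass(frozen=True)
class ClusterSet:
    """An ordered collection of ortholog clusters.

    Invariants enforced at construction: unique cluster ids, every
    (genome, gene) pair belongs to at most one cluster, every cluster
    is non-empty.
    """

    clusters: tuple[Cluster, ...]

    def __post_init__(self):
        seen_ids: set[str] = set()
        seen_members: set[tuple[str, str]] = set()
        for cl in self.clusters:
            if cl.id in seen_ids:
                raise ValueError(f"duplicate cluster id {cl.id!r}")
            seen_ids.add(cl.id)
            dup = seen_members & cl.members
            if dup:
                g, gene = sorted(dup)[0]
                raise ValueError(
                    f"member {g}|{gene} appears in more than one cluster"
                )
            seen_members |= cl.members

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def genomes(self) -> list[str]:
        """Sorted list of every genome id referenced by any cluster."""
        out: set[str] = set()
        for cl in self.clusters:
            out |= cl.genomes
        return sorted(out)


@dataclass(frozen=True)
class CompartmentLabels:
    """Immutable genome_id -> compartment map."""

    mapping: Mapping[str, str]

    def __post_init__(self):
        bad = {s: c for s, c in self.mapping.items() if c not in COMPARTMENTS}
        if bad:
            raise ValueError(
                f"unknown compartment(s): {sorted(set(bad.values()))}; "
                f"expected one of {COMPARTMENTS}"
            )
        object.__setattr__(self, "mapping", dict(self.mapping))

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, strain: str) -> bool:
        return strain in self.mapping

    def __getitem__(self, strain: str) -> str:
        return self.mapping[strain]

    @property
    def strains(self) -> list[str]:
        return list(self.mapping)

    def strains_in(self, compartment: str) -> list[str]:
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
        return [s for s, c in self.mapping.items() if c == compartment]

    def split(self, strains: Iterable[str]) -> tuple[list[str], list[str]]:
        """Partition ``strains`` (order preserved) into (rhizosphere, endosphere)."""
        r, e = [], []
        for s in strains:
            if s not in self.mapping:
                raise ConsistencyError(f"strain {s!r} has no compartment label")
            (r if self.mapping[s] == RHIZOSPHERE else e).append(s)
        return r, e

    def require_cover(self, strains: Iterable[str]) -> None:
        """Raise if any strain is unlabelled, listing every offender."""
        missing = [s for s in strains if s not in self.mapping]
        if missing:
            raise ConsistencyError(
                "strains missing from compartment labels: "
                + ", ".join(sorted(missing))
            )

    def require_both_compartments(self, strains: Iterable[str]) -> None:
        """Raise unless ``strains`` contains at least one strain per compartment."""
        strains = list(strains)
        r, e = self.split(strains)
        if not r or not e:
            empty = RHIZOSPHERE if not r else ENDOSPHERE
            raise ConsistencyError(
                f"compartment {empty!r} has no strains among {len(strains)} inputs"
            )


@dataclass(frozen=True)
class PresenceMatrix:
    """Binary strains x features matrix backed by a pandas DataFrame.

    ``data`` is indexed by strain id with feature ids as columns and
    int8 cells in {0, 1}. ``kind`` records what the features are (see
    ``MATRIX_KINDS``); it affects IO policy only, never arithmetic.
    """

    data: pd.DataFrame
    kind: str = "presence"

    def __post_init__(self):
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate strain id(s): {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature id(s): {dups}")
        vals = df.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("matrix cells must be 0 or 1")
        object.__setattr__(self, "data", df.astype(np.int8))

    @classmethod
    def from_arrays(
        cls,
        strains: Iterable[str],
        features: Iterable[str],
        values,
        kind: str = "presence",
    ) -> "PresenceMatrix":
        df = pd.DataFrame(
            np.asarray(values), index=list(strains), columns=list(features)
        )
        return cls(df, kind=kind)

    @property
    def strains(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def restrict(self, strains=None, features=None) -> "PresenceMatrix":
        """Sub-matrix on the given strains and/or features (order as given)."""
        df = self.data
        if strains is not None:
            missing = [s for s in strains if s not in df.index]
            if missing:
                raise KeyError(f"unknown strain(s): {missing}")
            df = df.loc[list(strains)]
        if features is not None:
            missing = [f for f in features if f not in df.columns]
            if missing:
                raise KeyError(f"unknown feature(s): {missing}")
            df = df[list(features)]
        return PresenceMatrix(df, kind=self.kind)

    def feature_vector(self, feature: str) -> np.ndarray:
        if feature not in self.data.columns:
            raise KeyError(f"unknown feature {feature!r}")
        return self.data[feature].to_numpy()

    def drop_empty_features(self) -> "PresenceMatrix":
        keep = self.data.columns[self.data.sum(axis=0) > 0]
        return PresenceMatrix(self.data[keep], kind=self.kind)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return self.kind == other.kind and self.data.equals(other.data)
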
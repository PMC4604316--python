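"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (parameters, seed): clusters with a
planted compartment Venn decomposition (exact mode) or Bernoulli
presence probabilities (stochastic mode), class-structured utilization
matrices with planted per-compartment effect sizes, noisy model
predictions, mutated marker-gene alignments and trait tables. Exact
mode exists so that downstream partition operations can be checked for
bit-perfect parameter recovery; Bernoulli mode feeds power and type-I
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .consensus import Alignment, BASES
from .io_cli.types import (
    Cluster,
    ClusterSet,
    CompartmentLabels,
    ENDOSPHERE,
    PresenceMatrix,
    RHIZOSPHERE,
)
from .pangenome import VENN_CELLS


@dataclass(frozen=True)
class ClassSpec:
    """One compound class: size and per-compartment utilization fractions."""

    name: str
    size: int
    frac_rhizosphere: float
    frac_endosphere: float

    def __post_init__(self):
        if self.size < 1:
            raise ValueError(f"class {self.name!r} has size < 1")
        for frac in (self.frac_rhizosphere, self.frac_endosphere):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"class {self.name!r} fraction {frac} outside [0, 1]"
                )


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters for a simulated input bundle."""

    n_rhizosphere: int = 4
    n_endosphere: int = 15
    # pan-genome: exact planted cell counts takes precedence over the
    # Bernoulli (core_size/accessory_size + probabilities) mode
    venn_counts: Mapping[tuple[str, str], int] | None = None
    core_size: int = 0
    accessory_size: int = 0
    p_rhizosphere: float = 0.5
    p_endosphere: float = 0.5
    # carbon utilization
    class_specs: tuple[ClassSpec, ...] = ()
    # traits: name -> (prevalence_R, prevalence_E)
    trait_prevalences: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )
    # model predictions
    prediction_error_rate: float = 0.0
    # marker-gene alignment
    consensus: str = ""
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rhizosphere < 0 or self.n_endosphere < 0:
            raise ValueError("group sizes must be >= 0")
        for p in (self.p_rhizosphere, self.p_endosphere,
                  self.prediction_error_rate, self.mutation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for name, (pr, pe) in self.trait_prevalences.items():
            if not (0.0 <= pr <= 1.0 and 0.0 <= pe <= 1.0):
                raise ValueError(f"trait {name!r} prevalence outside [0, 1]")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    @property
    def genome_ids(self) -> list[str]:
        return [f"R{i + 1:02d}" for i in range(self.n_rhizosphere)] + [
            f"E{i + 1:02d}" for i in range(self.n_endosphere)
        ]

    def labels(self) -> CompartmentLabels:
        mapping = {g: RHIZOSPHERE for g in self.genome_ids if g.startswith("R")}
        mapping.update(
            {g: ENDOSPHERE for g in self.genome_ids if g.startswith("E")}
        )
        return CompartmentLabels(mapping)

    @property
    def n_compounds(self) -> int:
        return sum(spec.size for spec in self.class_specs)


# ---------------------------------------------------------------------------
# occupancy helpers
# ---------------------------------------------------------------------------

def _pick_occupancy(
    members: Sequence[str], occupancy: str, rng: np.random.Generator
) -> list[str]:
    """A subset of ``members`` realizing the requested occupancy."""
    n = len(members)
    if occupancy == "all":
        if n == 0:
            raise ValueError("occupancy 'all' impossible for an empty group")
        return list(members)
    if occupancy == "none":
        return []
    if occupancy == "some":
        if n < 2:
            raise ValueError(
                f"occupancy 'some' impossible for a group of size {n}"
            )
        size = int(rng.integers(1, n))  # 1 .. n-1: proper, non-empty
        idx = rng.choice(n, size=size, replace=False)
        return [members[i] for i in sorted(idx)]
    raise ValueError(f"unknown occupancy {occupancy!r}")


def _planted_presence(
    labels: CompartmentLabels,
    category_counts: Mapping[tuple[str, str], int],
    rng: np.random.Generator,
    feature_prefix: str,
) -> PresenceMatrix:
    """Binary matrix whose columns realize exact per-cell occupancy counts."""
    r_strains = labels.strains_in(RHIZOSPHERE)
    e_strains = labels.strains_in(ENDOSPHERE)
    strains = r_strains + e_strains
    index = {s: i for i, s in enumerate(strains)}
    total = sum(category_counts.values())
    width = max(4, len(str(total)))
    values = np.zeros((len(strains), total), dtype=np.int8)
    features = []
    j = 0
    for cell in VENN_CELLS:
        for _ in range(int(category_counts.get(cell, 0))):
            occ_r, occ_e = cell
            present = _pick_occupancy(r_strains, occ_r, rng)
            present += _pick_occupancy(e_strains, occ_e, rng)
            for s in present:
                values[index[s], j] = 1
            features.append(f"{feature_prefix}{j + 1:0{width}d}")
            j += 1
    return PresenceMatrix.from_arrays(strains, features, values,
                                      kind="presence")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_pangenome(
    truth: SimTruth,
) -> tuple[ClusterSet, CompartmentLabels, SimTruth]:
    """Ortholog clusters with a planted compartment structure.

    Exact mode (``truth.venn_counts`` set) realizes the requested Venn
    cell counts column by column; Bernoulli mode emits ``core_size``
    clusters present everywhere plus ``accessory_size`` clusters whose
    per-genome presence is Bernoulli with the compartment probability
    (resampled until non-empty, so every cluster has a member).
    """
    labels = truth.labels()
    rng = np.random.default_rng(truth.seed)
    genomes = truth.genome_ids
    if truth.venn_counts is not None:
        presence = _planted_presence(labels, truth.venn_counts, rng, "clu")
        arr = presence.values
        strains = presence.strains
        clusters = []
        for j, cid in enumerate(presence.features):
            members = frozenset(
                (strains[i], f"{strains[i]}|{cid}")
                for i in np.nonzero(arr[:, j])[0]
            )
            clusters.append(Cluster(cid, members))
        return ClusterSet(tuple(clusters)), labels, truth

    n_total = truth.core_size + truth.accessory_size
    width = max(4, len(str(n_total)))
    clusters = []
    for j in range(truth.core_size):
        cid = f"clu{j + 1:0{width}d}"
        clusters.append(
            Cluster(cid, frozenset((g, f"{g}|{cid}") for g in genomes))
        )
    probs = np.array(
        [
            truth.p_rhizosphere if labels[g] == RHIZOSPHERE
            else truth.p_endosphere
            for g in genomes
        ]
    )
    for j in range(truth.accessory_size):
        cid = f"clu{truth.core_size + j + 1:0{width}d}"
        present = rng.random(len(genomes)) < probs
        while not present.any():
            present = rng.random(len(genomes)) < probs
        members = frozenset(
            (g, f"{g}|{cid}") for g, keep in zip(genomes, present) if keep
        )
        clusters.append(Cluster(cid, members))
    return ClusterSet(tuple(clusters)), labels, truth


def generate_utilization(
    truth: SimTruth,
) -> tuple[PresenceMatrix, dict[str, str], SimTruth]:
    """Class-structured Bernoulli utilization matrix.

    Cell (strain, compound) ~ Bernoulli(frac of the strain's compartment
    for the compound's class).
    """
    if not truth.class_specs:
        raise ValueError("truth.class_specs is empty")
    labels = truth.labels()
    strains = truth.genome_ids
    rng = np.random.default_rng(truth.seed)
    width = max(3, len(str(truth.n_compounds)))
    compounds: list[str] = []
    classes: dict[str, str] = {}
    probs = np.zeros((len(strains), truth.n_compounds))
    is_r = np.array([labels[s] == RHIZOSPHERE for s in strains])
    j = 0
    for spec in truth.class_specs:
        for _ in range(spec.size):
            cid = f"cpd{j + 1:0{width}d}"
            compounds.append(cid)
            classes[cid] = spec.name
            probs[is_r, j] = spec.frac_rhizosphere
            probs[~is_r, j] = spec.frac_endosphere
            j += 1
    values = (rng.random(probs.shape) < probs).astype(np.int8)
    matrix = PresenceMatrix.from_arrays(strains, compounds, values,
                                        kind="utilization")
    return matrix, classes, truth


def plant_group_partition(
    strains: Sequence[str],
    n_all: int,
    n_none: int,
    n_differential: int,
    seed: int = 0,
    feature_prefix: str = "cpd",
) -> PresenceMatrix:
    """Utilization matrix with exact all/none/differential column counts
    for the given strain group."""
    strains = list(strains)
    if not strains:
        raise ValueError("empty strain list")
    if n_differential > 0 and len(strains) < 2:
        raise ValueError("differential columns need at least two strains")
    rng = np.random.default_rng(seed)
    total = n_all + n_none + n_differential
    width = max(3, len(str(total)))
    values = np.zeros((len(strains), total), dtype=np.int8)
    j = 0
    for _ in range(n_all):
        values[:, j] = 1
        j += 1
    j += n_none  # all-zero columns
    for _ in range(n_differential):
        size = int(rng.integers(1, len(strains)))
        idx = rng.choice(len(strains), size=size, replace=False)
        values[idx, j] = 1
        j += 1
    features = [f"{feature_prefix}{i + 1:0{width}d}" for i in range(total)]
    return PresenceMatrix.from_arrays(strains, features, values,
                                      kind="utilization")


def plant_reaction_matrix(
    labels: CompartmentLabels,
    core: int,
    shared_non_core: int,
    rhizosphere_only: int,
    endosphere_only: int,
    seed: int = 0,
) -> PresenceMatrix:
    """Reaction presence matrix with exact category counts.

    ``shared_non_core`` columns land in the (some, some) cell,
    compartment-exclusive columns in (some, none) / (none, some); this
    requires at least two strains per compartment when the respective
    count is non-zero.
    """
    rng = np.random.default_rng(seed)
    counts = {
        ("all", "all"): core,
        ("some", "some"): shared_non_core,
        ("some", "none"): rhizosphere_only,
        ("none", "some"): endosphere_only,
    }
    matrix = _planted_presence(labels, counts, rng, "rxn")
    return PresenceMatrix(matrix.data, kind="presence")


def generate_predictions(
    obs: PresenceMatrix, error_rate: float, seed: int = 0
) -> PresenceMatrix:
    """Noisy copy of an observation matrix: each cell flipped
    independently with probability ``error_rate``."""
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate outside [0, 1]")
    rng = np.random.default_rng(seed)
    flips = rng.random(obs.shape) < error_rate
    values = np.where(flips, 1 - obs.values, obs.values)
    return PresenceMatrix.from_arrays(obs.strains, obs.features, values,
                                      kind="prediction")


def generate_alignment(
    consensus: str, n: int, mu: float, seed: int = 0
) -> Alignment:
    """``n`` sequences mutated from ``consensus``: each site substituted
    to a uniformly chosen different base with probability ``mu``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu outside [0, 1]")
    consensus = consensus.upper()
    bad = set(consensus) - set(BASES)
    if bad:
        raise ValueError(f"consensus contains non-ACGT symbols {sorted(bad)}")
    rng = np.random.default_rng(seed)
    base_arr = np.array(list(consensus))
    base_idx = np.searchsorted(np.array(BASES), base_arr)
    width = len(str(n))
    records = []
    for i in range(n):
        mutate = rng.random(len(consensus)) < mu
        # offset 1..3 modulo 4 guarantees a *different* base
        offsets = rng.integers(1, 4, size=len(consensus))
        new_idx = np.where(mutate, (base_idx + offsets) % 4, base_idx)
        seq = "".join(BASES[k] for k in new_idx)
        records.append((f"seq{i + 1:0{width}d}", seq))
    return Alignment(tuple(records))


def generate_traits(truth: SimTruth) -> PresenceMatrix:
    """Bernoulli trait table with per-compartment prevalences."""
    if not truth.trait_prevalences:
        raise ValueError("truth.trait_prevalences is empty")
    labels = truth.labels()
    strains = truth.genome_ids
    rng = np.random.default_rng(truth.seed)
    is_r = np.array([labels[s] == RHIZOSPHERE for s in strains])
    trait_ids = list(truth.trait_prevalences)
    probs = np.zeros((len(strains), len(trait_ids)))
    for j, tid in enumerate(trait_ids):
        pr, pe = truth.trait_prevalences[tid]
        probs[is_r, j] = pr
        probs[~is_r, j] = pe
    values = (rng.random(probs.shape) < probs).astype(np.int8)
    return PresenceMatrix.from_arrays(strains, trait_ids, values, kind="trait")


# ---------------------------------------------------------------------------
# study-shaped default profile
# ---------------------------------------------------------------------------

def load_profile(path=None) -> dict:
    """Load a simulation profile (YAML). Defaults to the bundled
    study-shaped profile: 4 + 15 strains, 190 compounds in 9 classes,
    a 1500-site marker gene."""
    if path is None:
        text = (
            resources.files("rhizopan.data")
            .joinpath("study_profile.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, "rt", encoding="utf-8") as fh:
            text = fh.read()
    return yaml.safe_load(text)


def truth_from_profile(profile: dict, seed: int = 0) -> SimTruth:
    """Build a :class:`SimTruth` from a profile dictionary."""
    venn = profile.get("venn_counts")
    venn_counts = None
    if venn:
        venn_counts = {
            (str(k.split("/")[0]), str(k.split("/")[1])): int(v)
            for k, v in venn.items()
        }
    class_specs = tuple(
        ClassSpec(
            name=c["name"], size=int(c["size"]),
            frac_rhizosphere=float(c["frac_rhizosphere"]),
            frac_endosphere=float(c["frac_endosphere"]),
        )
        for c in profile.get("classes", [])
    )
    rng = np.random.default_rng(seed)
    consensus = profile.get("consensus")
    if consensus is None:
        length = int(profile.get("marker_length", 1500))
        consensus = "".join(
            BASES[i] for i in rng.integers(0, 4, size=length)
        )
    traits = {
        t["name"]: (float(t["prevalence_rhizosphere"]),
                    float(t["prevalence_endosphere"]))
        for t in profile.get("traits", [])
    }
    return SimTruth(
        n_rhizosphere=int(profile.get("n_rhizosphere", 4)),
        n_endosphere=int(profile.get("n_endosphere", 15)),
        venn_counts=venn_counts,
        core_size=int(profile.get("core_size", 0)),
        accessory_size=int(profile.get("accessory_size", 0)),
        p_rhizosphere=float(profile.get("p_rhizosphere", 0.5)),
        p_endosphere=float(profile.get("p_endosphere", 0.5)),
        class_specs=class_specs,
        trait_prevalences=traits,
        prediction_error_rate=float(profile.get("prediction_error_rate", 0.0)),
        consensus=consensus,
        mutation_rate=float(profile.get("mutation_rate", 0.005)),
        seed=int(seed),
    )
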
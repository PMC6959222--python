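"""Synthetic inputs with the statistical structure the pipeline assumes.

Every pipeline stage is exercised on generated data carrying a known
ground truth: an interactome with a planted, loosely connected disease
module containing the seeds; term collections with hierarchy levels and
designated module-biased terms; a multi-label molecule library whose
activity labels follow planted substructure rules (plus optional label
noise); and a signed directed network wired so that a known set of
targets is sign-consistent with the disease alterations.

All generators are deterministic for a fixed ``rng_seed``: one seed
sequence per run, with fixed per-generator substreams, so cross-module
fixtures reproduce exactly.  Each generator returns a ground-truth
manifest sufficient for parameter-recovery tests.

Default scales (1,000-node network, 50-protein module with 40% of it
seeded, 200 molecules) keep a full run in seconds while leaving the
planted signals clearly recoverable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem

from netprev.enrichment import TermGeneSet
from netprev.interactome import EVIDENCE_TYPES
from netprev.mechanisms import add_signed_edge
from netprev.revpharm.molecules import Molecule

# Fixed substream indices so each generator draws from its own stream.
_STREAM_NETWORK = 0
_STREAM_ANNOTATIONS = 1
_STREAM_CHEMISTRY = 2
_STREAM_SIGNED = 3


@dataclass
class NetworkConfig:
    n_nodes: int = 1000
    attachment_m: int = 2          # preferential-attachment edges per new node
    module_size: int = 50
    p_intra: float = 0.15          # intra-module edge probability (sub-clique)
    seed_fraction: float = 0.4     # fraction of module members marked as seeds

    def __post_init__(self):
        if not 0 < self.module_size < self.n_nodes:
            raise ValueError("module size must lie strictly inside the network")
        if not 0.0 <= self.p_intra <= 1.0:
            raise ValueError("p_intra must be a probability")
        if not 0.0 < self.seed_fraction <= 1.0:
            raise ValueError("seed_fraction must be in (0, 1]")


@dataclass
class AnnotationConfig:
    n_terms: int = 60
    term_size_range: tuple[int, int] = (10, 40)
    hierarchy_depth: int = 5
    n_module_biased: int = 5
    bias_fraction: float = 0.7     # fraction of a biased term drawn from the module


@dataclass
class ChemistryConfig:
    n_molecules: int = 200
    activities: tuple[str, ...] = ("ACHE inhibitor", "BCHE inhibitor")
    active_fraction: float = 0.35  # molecules carrying some planted substructure
    label_noise: float = 0.0       # probability of flipping each activity label
    n_plants: int = 30
    size_range: tuple[int, int] = (8, 18)   # heavy atoms in the scaffold
    # quotas of deliberately ineligible molecules (added on top of n_molecules)
    n_too_small: int = 0
    n_charged: int = 0
    n_multicomponent: int = 0
    n_too_heavy: int = 0


@dataclass
class SignedNetConfig:
    n_consistent_targets: int = 3
    n_scrambled_targets: int = 3
    endpoints_per_target: int = 6
    p_two_edge: float = 0.5        # fraction of paths routed via an intermediate
    p_inhibiting: float = 0.5      # sign balance of edges


@dataclass
class GeneratorConfig:
    rng_seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    annotations: AnnotationConfig = field(default_factory=AnnotationConfig)
    chemistry: ChemistryConfig = field(default_factory=ChemistryConfig)
    signed_net: SignedNetConfig = field(default_factory=SignedNetConfig)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        return cls(
            rng_seed=int(d.get("rng_seed", 0)),
            network=NetworkConfig(**d.get("network", {})),
            annotations=AnnotationConfig(**_tupled(d.get("annotations", {}), "term_size_range")),
            chemistry=ChemistryConfig(**_tupled(d.get("chemistry", {}), "activities", "size_range")),
            signed_net=SignedNetConfig(**d.get("signed_net", {})),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _tupled(d: Mapping, *keys: str) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.rng_seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Interactome with a planted disease module


def gen_interactome(config: GeneratorConfig) -> tuple[nx.Graph, dict]:
    """Preferential-attachment background with a planted disease module.

    The module is wired at elevated — but far below clique — density,
    reflecting the observation that disease proteins cluster loosely
    rather than forming dense functional modules.  A configured fraction
    of module members is marked as known seeds.

    Returns the graph and a ground-truth manifest with keys
    ``module_members``, ``seeds``, ``n_nodes``, ``n_edges``.
    """
    nc = config.network
    rng = _rng(config, _STREAM_NETWORK)
    base = nx.barabasi_albert_graph(
        nc.n_nodes, nc.attachment_m, seed=int(rng.integers(2**31))
    )
    width = len(str(nc.n_nodes))
    names = {i: f"P{i:0{width}d}" for i in base.nodes()}
    graph = nx.Graph()
    graph.add_nodes_from(names.values())
    types = sorted(EVIDENCE_TYPES)
    for a, b in base.edges():
        etype = types[rng.integers(len(types))]
        graph.add_edge(names[a], names[b], types={etype})

    members = sorted(
        names[i] for i in rng.choice(nc.n_nodes, size=nc.module_size, replace=False)
    )
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if not graph.has_edge(members[i], members[j]) and rng.random() < nc.p_intra:
                graph.add_edge(members[i], members[j], types={"ppi"})
    n_seeds = max(1, round(nc.seed_fraction * nc.module_size))
    seeds = sorted(rng.choice(members, size=n_seeds, replace=False).tolist())
    truth = {
        "module_members": members,
        "seeds": seeds,
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
    }
    return graph, truth


# ---------------------------------------------------------------------------
# Term collections


def gen_annotations(
    config: GeneratorConfig, graph_truth: Mapping
) -> tuple[list[TermGeneSet], dict]:
    """Term-gene collection over the interactome's gene universe.

    The first ``n_module_biased`` terms draw ``bias_fraction`` of their
    genes from the planted module (and are assigned levels deep enough to
    survive the usual level filter); the rest are uniform draws from the
    whole universe with uniform levels 1..depth.
    """
    ac = config.annotations
    rng = _rng(config, _STREAM_ANNOTATIONS)
    module = list(graph_truth["module_members"])
    n_nodes = int(graph_truth["n_nodes"])
    width = len(str(n_nodes))
    universe = [f"P{i:0{width}d}" for i in range(n_nodes)]
    background = [g for g in universe if g not in set(module)]
    lo, hi = ac.term_size_range
    terms: list[TermGeneSet] = []
    biased: list[str] = []
    for t in range(ac.n_terms):
        size = int(rng.integers(lo, hi + 1))
        term_id = f"T{t:04d}"
        if t < ac.n_module_biased:
            n_mod = min(len(module), max(1, round(ac.bias_fraction * size)))
            genes = list(rng.choice(module, size=n_mod, replace=False))
            genes += list(rng.choice(background, size=size - n_mod, replace=False))
            level = int(rng.integers(3, ac.hierarchy_depth + 1)) if ac.hierarchy_depth >= 3 else ac.hierarchy_depth
            biased.append(term_id)
        else:
            genes = list(rng.choice(universe, size=size, replace=False))
            level = int(rng.integers(1, ac.hierarchy_depth + 1))
        terms.append(
            TermGeneSet(term_id=term_id, name=f"synthetic term {t}", level=level, genes=frozenset(genes))
        )
    return terms, {"biased_terms": biased, "universe_size": len(universe)}


# ---------------------------------------------------------------------------
# Molecule library with planted substructure-activity rules

# Motifs planted into active molecules.  They use elements absent from the
# background scaffold alphabet (C/N/O), so a motif can never arise by
# chance in an inactive molecule.
_MOTIF_BANK = ("S", "P", "F", "Cl", "Br", "I")
_SCAFFOLD_ELEMENTS = ("C", "C", "C", "C", "C", "N", "O")  # sampling weights
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "F": 1, "Cl": 1, "Br": 1, "I": 1}


def _random_scaffold(
    rng: np.random.Generator, n_atoms: int, motifs: Sequence[str] = ()
) -> Chem.Mol:
    """Random valence-respecting tree molecule over C/N/O, with optional
    planted marker fragments attached at random positions.

    A motif is a three-atom fragment built from its marker element M:
    ``-M-C-M`` for divalent/trivalent markers (S, P) and ``-C(M)(M)M``
    for monovalent halogens.  Either way the fragment contributes atom
    neighbourhoods that can never arise from the C/N/O background.
    """
    rw = Chem.RWMol()
    symbols = ["C"]
    rw.AddAtom(Chem.Atom("C"))
    used = [0]  # bonds used per atom

    def add_atom(sym: str, parent: int) -> int:
        idx = rw.AddAtom(Chem.Atom(sym))
        rw.AddBond(parent, idx, Chem.BondType.SINGLE)
        symbols.append(sym)
        used.append(1)
        used[parent] += 1
        return idx

    for _ in range(n_atoms - 1):
        sym = _SCAFFOLD_ELEMENTS[rng.integers(len(_SCAFFOLD_ELEMENTS))]
        open_idx = [i for i, s in enumerate(symbols) if used[i] < _MAX_VALENCE[s]]
        parent = int(open_idx[rng.integers(len(open_idx))])
        add_atom(sym, parent)

    for marker in motifs:
        open_idx = [i for i, s in enumerate(symbols) if used[i] < _MAX_VALENCE[s] and s == "C"]
        if not open_idx:
            open_idx = [i for i, s in enumerate(symbols) if used[i] < _MAX_VALENCE[s]]
        parent = int(open_idx[rng.integers(len(open_idx))])
        if _MAX_VALENCE[marker] >= 2:
            m1 = add_atom(marker, parent)
            c = add_atom("C", m1)
            add_atom(marker, c)
        else:
            c = add_atom("C", parent)
            for _ in range(3):
                add_atom(marker, c)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def gen_molecules(
    config: GeneratorConfig,
) -> tuple[list[Molecule], pd.DataFrame, dict[str, list[str]], dict]:
    """Molecule library with planted substructure-activity labels.

    Each activity owns a marker element from a bank of elements absent
    from the background C/N/O scaffolds; a molecule is truly active for
    an activity iff its marker atom was attached at build time.  Observed
    labels equal true labels XOR independent flips at ``label_noise``.
    Deliberately ineligible molecules (too small, charged,
    multi-component, too heavy) are appended per the configured quotas.

    Returns (molecules, observed 0/1 label frame indexed by mol_id,
    plant -> molecule ids map, ground-truth manifest).
    """
    cc = config.chemistry
    rng = _rng(config, _STREAM_CHEMISTRY)
    if len(cc.activities) > len(_MOTIF_BANK):
        raise ValueError(f"at most {len(_MOTIF_BANK)} activities supported")
    motif_of = {a: _MOTIF_BANK[i] for i, a in enumerate(cc.activities)}

    molecules: list[Molecule] = []
    true_labels: dict[str, dict[str, int]] = {}
    lo, hi = cc.size_range
    for i in range(cc.n_molecules):
        mol_id = f"M{i:04d}"
        n_atoms = int(rng.integers(lo, hi + 1))
        active_for: list[str] = []
        if rng.random() < cc.active_fraction and cc.activities:
            active_for = [cc.activities[int(rng.integers(len(cc.activities)))]]
        extra = [motif_of[a] for a in active_for]
        mol = _random_scaffold(rng, n_atoms, extra)
        smiles = Chem.MolToSmiles(mol)
        molecules.append(Molecule(mol_id=mol_id, mol=mol, smiles=smiles))
        true_labels[mol_id] = {a: int(a in active_for) for a in cc.activities}

    ineligible: list[str] = []
    def _add_special(smiles: str, tag: str, j: int):
        mol_id = f"X{tag}{j:02d}"
        molecules.append(Molecule.from_smiles(mol_id, smiles))
        true_labels[mol_id] = {a: 0 for a in cc.activities}
        ineligible.append(mol_id)

    for j in range(cc.n_too_small):
        _add_special("CC", "S", j)                       # ethane, 30 Da
    for j in range(cc.n_charged):
        _add_special("CCC(=O)[O-]", "C", j)              # propanoate anion
    for j in range(cc.n_multicomponent):
        _add_special("CCO.CCN", "M", j)                  # two components
    for j in range(cc.n_too_heavy):
        _add_special("C" * 95, "H", j)                   # ~1333 Da alkane

    observed = {}
    for mol_id, row in true_labels.items():
        observed[mol_id] = {
            a: v ^ int(rng.random() < cc.label_noise) for a, v in row.items()
        }
    labels = pd.DataFrame.from_dict(observed, orient="index").sort_index()
    labels = labels[list(cc.activities)] if cc.activities else labels

    plant_map: dict[str, list[str]] = {f"plant{p:03d}": [] for p in range(cc.n_plants)}
    plant_names = sorted(plant_map)
    for m in molecules:
        plant = plant_names[int(rng.integers(len(plant_names)))]
        plant_map[plant].append(m.mol_id)
        m.source_plant_ids = (plant,)

    truth = {
        "motif_of": motif_of,
        "true_labels": {m: dict(r) for m, r in true_labels.items()},
        "ineligible": ineligible,
    }
    return molecules, labels, plant_map, truth


# ---------------------------------------------------------------------------
# Signed directed network with planted consistent targets


def gen_signed_network(
    config: GeneratorConfig,
    targets: Sequence[str] | None = None,
    endpoint_names: Sequence[str] | None = None,
    intervention_signs: Mapping[str, int] | None = None,
) -> tuple[nx.MultiDiGraph, dict[str, int], dict]:
    """Signed digraph wired so planted targets oppose the disease.

    For each *consistent* target, every endpoint's disease direction is
    set to the negative of (intervention sign x path sign product), so
    each of its <= 2-edge paths is sign-consistent by construction.
    *Scrambled* targets get uniformly random endpoint directions instead.
    Endpoint sets are disjoint across targets so their annotations never
    conflict.

    Optional ``targets``/``endpoint_names`` reuse identifiers from the
    interactome (first the consistent, then the scrambled targets).

    Returns (graph, alteration map, manifest with ``consistent_targets``,
    ``scrambled_targets`` and per-target ``intervention_sign``).
    """
    sc = config.signed_net
    rng = _rng(config, _STREAM_SIGNED)
    n_targets = sc.n_consistent_targets + sc.n_scrambled_targets
    if targets is not None:
        if len(targets) < n_targets:
            raise ValueError(f"need {n_targets} target names, got {len(targets)}")
        target_names = list(targets[:n_targets])
    else:
        target_names = [f"TGT{i:02d}" for i in range(n_targets)]
    consistent = target_names[: sc.n_consistent_targets]
    scrambled = target_names[sc.n_consistent_targets :]

    n_endpoints = n_targets * sc.endpoints_per_target
    if endpoint_names is not None:
        if len(endpoint_names) < n_endpoints:
            raise ValueError(f"need {n_endpoints} endpoint names, got {len(endpoint_names)}")
        endpoints = list(endpoint_names[:n_endpoints])
    else:
        endpoints = [f"DIS{i:03d}" for i in range(n_endpoints)]

    graph = nx.MultiDiGraph()
    alteration: dict[str, int] = {}
    intervention: dict[str, int] = {}
    e_idx = 0
    inter_idx = 0
    for t_idx, target in enumerate(target_names):
        if intervention_signs is not None and target in intervention_signs:
            sign_t = intervention_signs[target]
        else:
            sign_t = -1 if rng.random() < 0.5 else +1
        intervention[target] = sign_t
        for _ in range(sc.endpoints_per_target):
            endpoint = endpoints[e_idx]
            e_idx += 1
            signs = []
            if rng.random() < sc.p_two_edge:
                mid = f"INT{inter_idx:03d}"
                inter_idx += 1
                signs = [
                    -1 if rng.random() < sc.p_inhibiting else +1,
                    -1 if rng.random() < sc.p_inhibiting else +1,
                ]
                add_signed_edge(graph, target, mid, signs[0])
                add_signed_edge(graph, mid, endpoint, signs[1])
            else:
                signs = [-1 if rng.random() < sc.p_inhibiting else +1]
                add_signed_edge(graph, target, endpoint, signs[0])
            product = signs[0] * (signs[1] if len(signs) > 1 else 1)
            if target in consistent:
                alteration[endpoint] = -(sign_t * product)
            else:
                alteration[endpoint] = -1 if rng.random() < 0.5 else +1
    truth = {
        "consistent_targets": consistent,
        "scrambled_targets": scrambled,
        "intervention_sign": intervention,
    }
    return graph, alteration, truth
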
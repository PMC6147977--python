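"""Synthetic data generators for every analysis stage.

Three experiment emulators and one sequence-evolution simulator:

* :func:`simulate_growth_kill` — deterministic bacteria/phage/antibiotic
  dynamics observed as plate-reader OD590 with multiplicative noise;
* :func:`simulate_one_step` — one-step growth curves with Poisson plaque
  counts (burst size / latent period);
* :func:`simulate_adsorption` — free-phage exponential decay with Poisson
  counts (adsorption rate);
* :func:`simulate_pangenome` — gene gain/loss and protein divergence along a
  guide tree, yielding proteomes with retained truth family labels.

The growth/kill model integrates susceptible (S), m sequential infected
stages (I_1..I_m, an Erlang-distributed latent period), phage-resistant (R)
and free-phage (P) compartments:

    dS/dt  = (1 - mu) g S - delta S P - kappa_S S
    dI_1   = delta S P - (m/tau) I_1 - kappa_I I_1
    dI_j   = (m/tau) (I_{j-1} - I_j) - kappa_I I_j
    dR/dt  = g R + mu g S - kappa_R R
    dP/dt  = beta (m/tau) I_m - delta S P

with logistic per-capita growth g = r (1 - N/K), N = S + sum I + R, and a
Hill-type antibiotic kill rate kappa = emax C^h / (ec50^h + C^h) applied to
dividing compartments (S, R) in the meropenem-like mode or to all cell
compartments in the colistin-like mode. OD590 = alpha * N + od0. Integration
is fixed-step classical RK4 with a configurable number of substeps per
output interval; compartments are clamped at 0 after each substep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from phagekit.datatypes import ODTimeSeries, Treatment

__all__ = [
    "GrowthKillParams",
    "GeneEvolutionParams",
    "integrate_growth_kill",
    "simulate_growth_kill",
    "simulate_one_step",
    "simulate_adsorption",
    "simulate_pangenome",
    "simulate_gene_tree_topologies",
    "growth_kill_derivative",
    "DEFAULT_GUIDE_TREE_NEWICK",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# growth / kill curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthKillParams:
    """Parameters of the bacteria-phage-antibiotic dynamic model.

    Defaults emulate an *A. baumannii*-like host in a 16 h microplate assay:
    the untreated culture saturates near OD 0.5 and the phage has a burst
    size of 39 and a 30 min latent period.
    """

    r: float = 1.4            # intrinsic growth rate (1/h)
    K: float = 1e9            # carrying capacity (cells/ml)
    delta: float = 3e-9       # adsorption rate constant (ml/h per phage)
    beta: float = 39.0        # burst size (phage per lysed cell)
    tau: float = 0.5          # latent period (h), Erlang with m_stages
    m_stages: int = 5         # number of sequential infected stages
    emax: float = 2.0         # maximal antibiotic kill rate (1/h)
    ec50: float = 64.0        # concentration of half-maximal kill (mg/l)
    hill: float = 2.0         # Hill exponent
    mu: float = 1e-10         # per-division phage-resistance mutation prob.
    alpha: float = 4.5e-10    # OD590 per cell (OD*ml/cell)
    od0: float = 0.05         # background OD offset
    kill_mode: str = "dividing"  # "dividing" (meropenem-like) | "all" (colistin-like)

    def __post_init__(self) -> None:
        for name in ("r", "K", "delta", "tau", "emax", "ec50", "hill",
                     "alpha", "od0"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.beta < 1:
            raise ValueError(f"beta must be >= 1, got {self.beta}")
        if not 0 <= self.mu <= 1:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if self.m_stages < 1:
            raise ValueError(f"m_stages must be >= 1, got {self.m_stages}")
        if self.kill_mode not in ("dividing", "all"):
            raise ValueError(
                f"kill_mode must be 'dividing' or 'all', got {self.kill_mode!r}"
            )


def _kill_rate(p: GrowthKillParams, concentration: float) -> float:
    if concentration <= 0 or p.emax == 0:
        return 0.0
    ch = concentration ** p.hill
    return p.emax * ch / (p.ec50 ** p.hill + ch)


def growth_kill_derivative(
    y: np.ndarray, p: GrowthKillParams, kappa: float
) -> np.ndarray:
    """Time derivative of the state [S, I_1..I_m, R, P, lysed, adsorbed].

    ``lysed`` and ``adsorbed`` are cumulative bookkeeping integrals used for
    conservation checks (phage produced = beta * cells lysed).
    """
    m = p.m_stages
    S = y[0]
    I = y[1:1 + m]
    R = y[1 + m]
    P = y[2 + m]
    N = S + I.sum() + R
    g = p.r * (1.0 - N / p.K)
    growth_pos = max(g, 0.0)
    adsorb = p.delta * S * P
    stage_rate = m / p.tau
    lysis = stage_rate * I[m - 1]

    kappa_div = kappa
    kappa_inf = kappa if p.kill_mode == "all" else 0.0

    dy = np.empty_like(y)
    dy[0] = g * S - p.mu * growth_pos * S - adsorb - kappa_div * S
    dy[1] = adsorb - stage_rate * I[0] - kappa_inf * I[0]
    for j in range(1, m):
        dy[1 + j] = stage_rate * (I[j - 1] - I[j]) - kappa_inf * I[j]
    dy[1 + m] = g * R + p.mu * growth_pos * S - kappa_div * R
    dy[2 + m] = p.beta * lysis - adsorb
    dy[3 + m] = lysis
    dy[4 + m] = adsorb
    return dy


def integrate_growth_kill(
    params: GrowthKillParams,
    treatment: Treatment,
    duration: float = 16.0,
    dt: float = 1.0 / 3.0,
    s0: float = 2.5e8,
    substeps: int = 20,
) -> dict:
    """Deterministic (noise-free) trajectory of the growth/kill model.

    Returns a dict with the output time grid and the S, I (total), R, P
    trajectories, cumulative lysed/adsorbed counts and the noise-free OD.
    Fixed-step RK4 with ``substeps`` internal steps per output interval.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    n_steps = duration / dt
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"duration ({duration}) must be an integral multiple of dt ({dt})"
        )
    n_steps = int(round(n_steps))
    if s0 <= 0:
        raise ValueError(f"s0 must be > 0, got {s0}")

    m = params.m_stages
    kappa = _kill_rate(params, treatment.concentration)
    y = np.zeros(5 + m)
    y[0] = s0
    y[2 + m] = treatment.moi * s0  # initial free phage

    times = np.arange(n_steps + 1) * dt
    out = np.empty((n_steps + 1, 5 + m))
    out[0] = y
    h = dt / substeps
    for i in range(n_steps):
        for _ in range(substeps):
            k1 = growth_kill_derivative(y, params, kappa)
            k2 = growth_kill_derivative(y + 0.5 * h * k1, params, kappa)
            k3 = growth_kill_derivative(y + 0.5 * h * k2, params, kappa)
            k4 = growth_kill_derivative(y + h * k3, params, kappa)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            np.maximum(y, 0.0, out=y)
        out[i + 1] = y

    cells = out[:, 0] + out[:, 1:1 + m].sum(axis=1) + out[:, 1 + m]
    return {
        "times": times,
        "S": out[:, 0],
        "I": out[:, 1:1 + m].sum(axis=1),
        "R": out[:, 1 + m],
        "P": out[:, 2 + m],
        "lysed": out[:, 3 + m],
        "adsorbed": out[:, 4 + m],
        "cells": cells,
        "od": params.alpha * cells + params.od0,
    }


def simulate_growth_kill(
    params: GrowthKillParams,
    treatments: list[Treatment],
    duration: float = 16.0,
    dt: float = 1.0 / 3.0,
    n_reps: int = 3,
    seed: int = 0,
    noise_sigma: float = 0.01,
    s0: float = 2.5e8,
    substeps: int = 20,
) -> list[ODTimeSeries]:
    """Simulate OD590 kill curves for each treatment x replicate.

    The deterministic model is integrated once per treatment; replicates
    differ by multiplicative Gaussian observation noise
    ``od * (1 + sigma * z)`` (plate-reader-like), clipped at 0.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    series: list[ODTimeSeries] = []
    for treatment in treatments:
        traj = integrate_growth_kill(
            params, treatment, duration=duration, dt=dt, s0=s0,
            substeps=substeps,
        )
        series.extend(
            observe_replicates(traj, treatment, n_reps, noise_sigma, rng,
                               dt=dt)
        )
    return series


def observe_replicates(
    traj: dict,
    treatment: Treatment,
    n_reps: int,
    noise_sigma: float,
    rng: np.random.Generator,
    dt: float = 1.0 / 3.0,
) -> list[ODTimeSeries]:
    """Observe a deterministic trajectory as noisy plate-reader replicates
    (multiplicative Gaussian noise, clipped at 0)."""
    out = []
    for rep in range(n_reps):
        z = rng.standard_normal(len(traj["times"]))
        od = np.clip(traj["od"] * (1.0 + noise_sigma * z), 0.0, None)
        out.append(
            ODTimeSeries(treatment=treatment, replicate=rep,
                         times=traj["times"], od=od, dt=dt)
        )
    return out


# ---------------------------------------------------------------------------
# one-step growth and adsorption assays
# ---------------------------------------------------------------------------

DEFAULT_ONE_STEP_TIMES = tuple(range(0, 31, 5)) + tuple(range(40, 121, 10))


def one_step_expected_titer(
    t: np.ndarray, beta: float, tau_latent: float, titer0: float,
    rise_width: float = 2.0,
) -> np.ndarray:
    """Noise-free one-step growth curve (pfu/ml).

    A plateau at ``titer0`` rises sigmoidally (normal CDF, midpoint
    ``tau_latent``, width ``rise_width`` min) to ``beta * titer0``.
    """
    from scipy.stats import norm

    t = np.asarray(t, dtype=float)
    return titer0 * (1.0 + (beta - 1.0) * norm.cdf(t, loc=tau_latent,
                                                   scale=rise_width))


def simulate_one_step(
    beta: float = 39.0,
    tau_latent: float = 30.0,
    titer0: float = 1e3,
    sample_times: list[float] | None = None,
    noise: bool = True,
    seed: int = 0,
    n_reps: int = 3,
    plate_volume_ml: float = 0.1,
    rise_width: float = 2.0,
):
    """One-step growth experiment with Poisson-noised plaque counts.

    Triplicate samples on the classical schedule (every 5 min for 30 min,
    then every 10 min for 90 min); expected plaque counts are
    ``titer * plate_volume_ml`` and observed counts are Poisson draws,
    converted back to pfu/ml.
    """
    from phagekit.kinetics import OneStepGrowthData

    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    if titer0 <= 0:
        raise ValueError(f"titer0 must be > 0, got {titer0}")
    if sample_times is None:
        sample_times = list(DEFAULT_ONE_STEP_TIMES)
    if len(sample_times) == 0:
        raise ValueError("sample_times must not be empty")
    times = np.asarray(sample_times, dtype=float)
    expected = one_step_expected_titer(times, beta, tau_latent, titer0,
                                       rise_width=rise_width)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if noise:
        counts = rng.poisson(
            np.tile(expected[:, None], (1, n_reps)) * plate_volume_ml
        )
        titers = counts / plate_volume_ml
    else:
        titers = np.tile(expected[:, None], (1, n_reps))
    return OneStepGrowthData(
        times=times, titers=titers, dilution_factor=1e-4, moi_nominal=0.01
    )


def simulate_adsorption(
    k: float = None,
    p0: float = 5e3,
    times: list[float] | None = None,
    cell_density: float = 1e7,
    seed: int = 0,
    n_reps: int = 2,
    noise: bool = True,
    plate_volume_ml: float = 0.1,
):
    """Adsorption assay: free phage decay with duplicate Poisson counts.

    ``k`` is the adsorption rate constant in ml/min per cell; the effective
    first-order decay rate of free phage is ``k * cell_density`` (1/min).
    The default reproduces >99% adsorption by 12 min.
    """
    from phagekit.kinetics import AdsorptionData

    if k is None:
        k = np.log(100.0) / 12.0 / cell_density
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if p0 <= 0:
        raise ValueError(f"p0 must be > 0, got {p0}")
    if times is None:
        times = [0.0, 3.0, 6.0, 9.0, 12.0, 15.0]
    times = np.asarray(times, dtype=float)
    expected = p0 * np.exp(-k * cell_density * times)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if noise:
        counts = rng.poisson(
            np.tile(expected[:, None], (1, n_reps)) * plate_volume_ml
        )
        free = counts / plate_volume_ml
    else:
        free = np.tile(expected[:, None], (1, n_reps))
    return AdsorptionData(
        times=times, free_titers=free, cell_density=cell_density, p0=p0
    )


# ---------------------------------------------------------------------------
# pan-genome evolution
# ---------------------------------------------------------------------------

#: Default 6-taxon guide topology, shaped like the Tevenvirinae "Cluster A"
#: phage genomes the pipeline is designed around.
DEFAULT_GUIDE_TREE_NEWICK = (
    "((KARL-1:0.05,ZZ1:0.05):0.03,Acj9:0.07,"
    "((Acj61:0.05,Phage133:0.05):0.03,Ac42:0.07):0.02);"
)


@dataclass(frozen=True)
class GeneEvolutionParams:
    """Parameters of the tree-structured gene gain/loss simulator.

    The genome set evolves down ``guide_tree`` from a common ancestor:
    ``n_core`` families are present single-copy in every genome; accessory
    families are gained (Poisson ``gain_rate`` per branch) and lost
    (probability ``1 - exp(-loss_rate)`` per branch); each genome adds
    private singleton families (Poisson ``n_singletons_mean``). Protein
    sequences mutate i.i.d. per site with per-branch probability
    ``divergence`` over the 20-letter amino-acid alphabet (no indels).
    Defaults give a desk-scale analogue of a six-phage cluster with a
    core/accessory/singleton structure.
    """

    guide_tree_newick: str = DEFAULT_GUIDE_TREE_NEWICK
    n_core: int = 40
    gain_rate: float = 3.0
    loss_rate: float = 0.2
    n_singletons_mean: float = 9.0
    prot_len: int = 200
    divergence: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core < 1:
            raise ValueError(f"n_core must be >= 1, got {self.n_core}")
        for name in ("gain_rate", "loss_rate", "n_singletons_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.divergence < 1:
            raise ValueError(
                f"divergence must be in [0, 1), got {self.divergence}"
            )
        if self.prot_len < 10:
            raise ValueError(f"prot_len must be >= 10, got {self.prot_len}")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(
        AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), length)
    )


def _mutate(rng: np.random.Generator, seq: str, p: float) -> str:
    if p == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < p)[0]
    if len(hits):
        subs = rng.integers(0, len(AMINO_ACIDS), len(hits))
        arr[hits] = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)[subs]
    return arr.tobytes().decode()


def simulate_pangenome(params: GeneEvolutionParams):
    """Evolve a phage genome set along the guide tree.

    Returns a :class:`~phagekit.pangenome.PhageGenomeSet` whose ``truth``
    maps each qualified gene id (``genome|gene``) to its true family label.
    A warning is emitted when the chosen divergence can push within-family
    identity below the default 0.5 clustering threshold across the deepest
    leaf-to-leaf paths (families become unrecoverable by design).
    """
    import dendropy

    from phagekit.pangenome import PhageGenomeSet

    tree = dendropy.Tree.get(data=params.guide_tree_newick, schema="newick")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise ValueError("guide tree leaf labels must be unique")

    # deepest root-to-leaf path in branch count, for the recoverability check
    def depth(node):
        kids = node.child_nodes()
        return 0 if not kids else 1 + max(depth(c) for c in kids)

    max_path = 2 * depth(tree.seed_node)
    if params.divergence > 0 and (1 - params.divergence * (1 - 1 / 20)) ** max_path < 0.5:
        warnings.warn(
            "divergence is high enough that within-family identity may fall "
            "below the default clustering threshold (0.5); families may be "
            "unrecoverable by design",
            stacklevel=2,
        )

    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    fam_counter = 0

    def new_family(prefix: str) -> tuple[str, str]:
        nonlocal fam_counter
        fam_counter += 1
        return f"{prefix}{fam_counter:04d}", _random_protein(rng, params.prot_len)

    # ancestral state: core families + a seed pool of accessory families
    ancestral: dict[str, str] = {}
    for _ in range(params.n_core):
        fam, seq = new_family("core")
        ancestral[fam] = seq
    n_acc0 = rng.poisson(params.gain_rate)
    for _ in range(n_acc0):
        fam, seq = new_family("acc")
        ancestral[fam] = seq

    core_ids = {f for f in ancestral if f.startswith("core")}
    p_loss = 1.0 - np.exp(-params.loss_rate)

    genomes: dict[str, list[tuple[str, str]]] = {}
    truth: dict[str, str] = {}

    def descend(node, state: dict[str, str]) -> None:
        state = dict(state)
        if node.parent_node is not None:  # apply branch events
            # substitutions
            state = {
                fam: _mutate(rng, seq, params.divergence)
                for fam, seq in state.items()
            }
            # accessory losses
            for fam in [f for f in state if f not in core_ids]:
                if rng.random() < p_loss:
                    del state[fam]
            # accessory gains
            for _ in range(rng.poisson(params.gain_rate)):
                fam, seq = new_family("acc")
                state[fam] = seq
        if node.is_leaf():
            label = node.taxon.label
            genes = []
            for i, (fam, seq) in enumerate(sorted(state.items())):
                gid = f"g{i + 1:04d}"
                genes.append((gid, seq))
                truth[f"{label}|{gid}"] = fam
            # private singletons
            n_single = rng.poisson(params.n_singletons_mean)
            for j in range(n_single):
                fam, seq = new_family(f"single_{label}_")
                gid = f"s{j + 1:04d}"
                genes.append((gid, seq))
                truth[f"{label}|{gid}"] = fam
            genomes[label] = genes
        else:
            for child in node.child_nodes():
                descend(child, state)

    descend(tree.seed_node, ancestral)
    # keep the guide tree's leaf ordering for determinism
    genomes = {lbl: genomes[lbl] for lbl in leaves}
    return PhageGenomeSet(genomes=genomes, truth=truth)


# ---------------------------------------------------------------------------
# gene-tree topology noise (for consensus experiments)
# ---------------------------------------------------------------------------

def random_topology(labels: list[str], rng: np.random.Generator):
    """Uniform random unrooted binary topology by sequential addition."""
    from phagekit.phylo import UnrootedTree

    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    order = list(labels)
    # edges as (parent_repr) -- build a simple edge list then newick
    # represent the growing unrooted tree as a dict of adjacency
    next_internal = [0]

    def internal() -> str:
        next_internal[0] += 1
        return f"@{next_internal[0]}"

    adj: dict[str, set[str]] = {}

    def add_edge(a: str, b: str) -> None:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    c = internal()
    for lab in order[:3]:
        add_edge(c, lab)
    edges = [(c, lab) for lab in order[:3]]
    for lab in order[3:]:
        a, b = edges[rng.integers(0, len(edges))]
        adj[a].discard(b)
        adj[b].discard(a)
        mid = internal()
        add_edge(a, mid)
        add_edge(mid, b)
        add_edge(mid, lab)
        edges.remove((a, b))
        edges.extend([(a, mid), (mid, b), (mid, lab)])

    def newick(node: str, parent: str | None) -> str:
        kids = [n for n in adj[node] if n != parent]
        if not kids:
            return node
        return "(" + ",".join(newick(k, node) for k in kids) + ")"

    start = c
    return UnrootedTree.from_newick(newick(start, None) + ";")


def nni_neighbors(tree) -> list:
    """All nearest-neighbor-interchange (NNI) rearrangements of an
    unrooted tree: two distinct topologies per internal edge.

    The tree is rerooted at the tail of each internal edge so the two
    tail-side subtrees (including the former parent direction) are its
    children; one head-side subtree is then exchanged with each of them.
    """
    from phagekit.phylo import UnrootedTree

    out = []
    newick = tree.to_newick()
    base = UnrootedTree.from_newick(newick).dendropy_tree
    n_internal = sum(
        1 for e in base.preorder_edge_iter()
        if e.tail_node is not None
        and not e.head_node.is_leaf()
        and e.head_node is not base.seed_node
    )
    for idx in range(n_internal):
        for variant in (0, 1):
            t = UnrootedTree.from_newick(newick).dendropy_tree
            edges = [
                e for e in t.preorder_edge_iter()
                if e.tail_node is not None
                and not e.head_node.is_leaf()
                and e.head_node is not t.seed_node
            ]
            edge = edges[idx]
            head, tail = edge.head_node, edge.tail_node
            t.reroot_at_node(tail, update_bipartitions=False)
            head_kids = head.child_nodes()
            tail_kids = [c for c in tail.child_nodes() if c is not head]
            if len(tail_kids) < 2 or len(head_kids) < 2:
                continue
            a = head_kids[0]
            b = tail_kids[variant]
            head.remove_child(a)
            tail.remove_child(b)
            head.add_child(b)
            tail.add_child(a)
            out.append(UnrootedTree.from_newick(
                t.as_string(schema="newick")
            ))
    return out


def simulate_gene_tree_topologies(
    guide, n_trees: int, noise_prob: float, seed: int = 0,
    noise_model: str = "nni",
):
    """Gene-tree sample around a guide topology.

    Each tree is independently perturbed with probability ``noise_prob``:
    under the default ``"nni"`` model by one uniformly chosen
    nearest-neighbor interchange (a local estimation error, the way real
    gene-tree reconstruction errs); under ``"random"`` by replacement with
    a uniform random topology.
    """
    from phagekit.phylo import UnrootedTree

    if not 0 <= noise_prob <= 1:
        raise ValueError(f"noise_prob must be in [0, 1], got {noise_prob}")
    if noise_model not in ("nni", "random"):
        raise ValueError(f"unknown noise_model {noise_model!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = sorted(guide.leaf_labels())
    neighbors = nni_neighbors(guide) if noise_model == "nni" else None
    out = []
    for _ in range(n_trees):
        if rng.random() < noise_prob:
            if noise_model == "nni":
                out.append(neighbors[rng.integers(0, len(neighbors))])
            else:
                order = [labels[i] for i in rng.permutation(len(labels))]
                out.append(random_topology(order, rng))
        else:
            out.append(UnrootedTree.from_newick(guide.to_newick()))
    return out
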
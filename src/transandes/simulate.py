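"""Seeded generators for every input the pipeline consumes.

Provides pure-birth (Yule) ultrametric trees, forward simulation of
geographic range histories under the dispersal-extinction-cladogenesis
process (ground truth for the likelihood machinery and transition calls),
GTR+Gamma sequence alignments, and synthetic transition compendia with a
known statistical structure.  All generators are deterministic under a
fixed seed.

Defaults mirror the study system: three areas with the Amazon as the only
hub connection and ranges of at most two areas; a 22-tip tree with a crown
age near 13 Ma; mitochondrial-like GTR parameters; and compendium sizes of
52 Amazon-origin vs 35 Andes-origin transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg

from .dec import DECParams, RangeStateSpace, andes_amazon_space, build_rate_matrix
from .compendium import TransitionRecord, ANDES_TO_AMAZON, AMAZON_TO_ANDES
from .seqdiag import Alignment
from .timetree import TimeTree
from .transitions import BranchRangeCall

__all__ = [
    "TreeConfig", "DECConfig", "SeqConfig", "CompendiumConfig", "SimConfig",
    "DECHistory", "simulate_yule_tree", "simulate_dec_history",
    "simulate_alignment", "simulate_compendium", "true_transitions",
    "calls_from_truth",
]


@dataclass(frozen=True)
class TreeConfig:
    n_tips: int = 22
    birth_rate: float = 0.25  # per Ma; ~13 Ma expected crown age at 22 tips
    crown_age: Optional[float] = None

    def __post_init__(self):
        if self.n_tips < 2 or self.birth_rate <= 0:
            raise ValueError("need n_tips >= 2 and birth_rate > 0")


@dataclass(frozen=True)
class DECConfig:
    d: float = 0.05
    e: float = 0.02
    root_range: str = "A"


@dataclass(frozen=True)
class SeqConfig:
    length: int = 1140
    # exchangeabilities in (AC, AG, AT, CG, CT, GT) order; transition-biased
    exchangeabilities: tuple = (1.0, 6.0, 1.0, 1.0, 6.0, 1.0)
    base_frequencies: tuple = (0.307, 0.262, 0.125, 0.305)
    gamma_shape: float = 0.5
    rate_categories: int = 4
    annotate_codons: bool = False

    def __post_init__(self):
        # printed empirical frequencies are often rounded; allow slack and
        # renormalise downstream
        if abs(sum(self.base_frequencies) - 1.0) > 1e-2:
            raise ValueError("base frequencies must sum to 1")
        if self.gamma_shape <= 0 or self.rate_categories < 1:
            raise ValueError("invalid gamma rate configuration")


@dataclass(frozen=True)
class CompendiumConfig:
    n_amazon_origin: int = 52
    n_andes_origin: int = 35
    # lognormal age distributions per origin (Ma)
    mu_amazon: float = 1.20
    mu_andes: float = 1.45
    sigma: float = 0.80
    fraction_range_ages: float = 0.10
    fraction_undated: float = 0.02


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    tree: TreeConfig = field(default_factory=TreeConfig)
    dec: DECConfig = field(default_factory=DECConfig)
    seq: SeqConfig = field(default_factory=SeqConfig)
    compendium: CompendiumConfig = field(default_factory=CompendiumConfig)


# -- Yule trees -------------------------------------------------------------

def simulate_yule_tree(n_tips: int, birth_rate: float = 0.25,
                       crown_age: Optional[float] = None,
                       seed: int = 0) -> TimeTree:
    """Pure-birth ultrametric tree conditioned on the number of tips.

    Starting from the crown with two lineages, waiting times between
    speciation events are Exp(k * birth_rate); after reaching ``n_tips``
    lineages, an Exp(n * birth_rate) interval separates the last split from
    the present.  If ``crown_age`` is given, all node times are rescaled so
    the crown sits exactly there.
    """
    cfg = TreeConfig(n_tips, birth_rate, crown_age)
    rng = np.random.default_rng(seed)
    t = 0.0
    split_times = [0.0]
    for k in range(2, cfg.n_tips):
        t += rng.exponential(1.0 / (k * cfg.birth_rate))
        split_times.append(t)
    total = t + rng.exponential(1.0 / (cfg.n_tips * cfg.birth_rate))
    if cfg.crown_age is not None:
        scale = cfg.crown_age / total
        split_times = [s * scale for s in split_times]
        total *= scale

    class _Node:
        __slots__ = ("birth", "children", "label", "split")

        def __init__(self, birth):
            self.birth = birth
            self.children = None
            self.label = None
            self.split = None

    a, b = _Node(0.0), _Node(0.0)
    active = [a, b]
    for st in split_times[1:]:
        i = int(rng.integers(len(active)))
        parent = active.pop(i)
        parent.split = st
        parent.children = (_Node(st), _Node(st))
        active.extend(parent.children)
    for i, lin in enumerate(active):
        lin.label = f"t{i + 1}"

    def newick(node) -> str:
        if node.children is None:
            return f"{node.label}:{total - node.birth:.12g}"
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}):{node.split - node.birth:.12g}"

    return TimeTree.from_newick(f"({newick(a)},{newick(b)});")


# -- forward DEC simulation -------------------------------------------------

@dataclass
class BranchHistory:
    top_state: frozenset
    bottom_state: frozenset
    events: list  # (age Ma, from_state, to_state)
    rejections: int = 0  # survival-conditioning redraws of this branch


@dataclass
class DECHistory:
    """Ground-truth range history from forward simulation."""

    root_range: frozenset
    node_scenarios: dict  # tipset -> (ancestor, left_range, right_range)
    branches: dict  # tipset -> BranchHistory
    tip_ranges: dict  # label -> frozenset
    extinct: bool  # any lineage absorbed into the empty range

    def replay_tip_ranges(self) -> dict:
        """Recompute tip ranges from recorded scenarios and events."""
        out = {}
        for tips, bh in self.branches.items():
            if len(tips) == 1:
                state = bh.top_state
                for _, frm, to in sorted(bh.events, key=lambda x: -x[0]):
                    assert frm == state
                    state = to
                out[next(iter(tips))] = state
        return out


def _tipset(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def simulate_dec_history(tree: TimeTree, space: Optional[RangeStateSpace],
                         params: DECParams, root_range,
                         seed: int = 0,
                         condition_on_survival: bool = False) -> DECHistory:
    """Gillespie simulation of range evolution along the tree.

    Anagenetic gains occur at rate d x (occupied areas adjacent to the
    target) into allowed states, losses at rate e per occupied area; at
    each node a cladogenetic outcome is drawn uniformly from the DEC
    scenario set of the current range.  By default lineages reaching the
    empty range stay empty (no conditioning on survival) and the replicate
    is flagged ``extinct``.  With ``condition_on_survival`` each branch's
    evolution is redrawn until its endpoint is non-empty — a local
    rejection step that keeps every tip observable (the number of
    rejections is recorded on each :class:`BranchHistory`).
    """
    space = space if space is not None else andes_amazon_space()
    if isinstance(root_range, str):
        root_range = space.parse_range(root_range)
    if root_range not in space.index or not root_range:
        raise ValueError("root range must be an allowed non-empty state")
    rng = np.random.default_rng(seed)
    Q = build_rate_matrix(space, params)
    from .dec import _cladogenetic_scenarios
    scen = _cladogenetic_scenarios(space)

    branches: dict[frozenset, BranchHistory] = {}
    node_scen: dict[frozenset, tuple] = {}
    tip_ranges: dict[str, frozenset] = {}
    extinct = False

    def evolve_once(state: frozenset, top_age: float, bot_age: float):
        events = []
        age = top_age
        while True:
            i = space.index[state]
            rate = -Q[i, i]
            if rate <= 0:
                break
            age = age - rng.exponential(1.0 / rate)
            if age <= bot_age:
                break
            probs = Q[i].clip(min=0)
            probs[i] = 0
            probs = probs / probs.sum()
            j = int(rng.choice(len(probs), p=probs))
            new = space.states[j]
            events.append((age, state, new))
            state = new
        return state, events

    def evolve(state: frozenset, top_age: float, bot_age: float):
        rejections = 0
        while True:
            end, events = evolve_once(state, top_age, bot_age)
            if end or not condition_on_survival:
                return end, events, rejections
            rejections += 1
            if rejections > 10_000:
                raise RuntimeError("survival conditioning failed to accept")

    def walk(node, incoming: frozenset):
        nonlocal extinct
        tips = _tipset(node)
        top_age = node.parent_node.age if node.parent_node is not None else node.age
        state, events, rej = (incoming, [], 0)
        if node.parent_node is not None:
            state, events, rej = evolve(incoming, top_age, node.age)
        branches[tips] = BranchHistory(incoming, state, events, rej)
        if not state:
            extinct = True
        if not node.child_nodes():
            tip_ranges[next(iter(tips))] = state
            return
        if state:
            outs = scen[state]
            k = int(rng.integers(len(outs)))
            left, right = outs[k]
        else:
            left = right = state
        node_scen[tips] = (state, left, right)
        c1, c2 = node.child_nodes()
        walk(c1, left)
        walk(c2, right)

    walk(tree.root, root_range)
    return DECHistory(root_range, node_scen, branches, tip_ranges, extinct)


def true_transitions(history: DECHistory, tree: TimeTree,
                     focal=("A", "B")) -> list[dict]:
    """Ground-truth focal-membership changes in a simulated history.

    Returns one entry per anagenetic event or cladogenetic outcome that
    changed membership in the focal region pair, with the polarity string
    in the same ``origin->destination`` form the detector emits.
    """
    F = frozenset(focal)
    out = []
    for tips, bh in history.branches.items():
        for age, frm, to in bh.events:
            if (frm & F) != (to & F):
                out.append({
                    "branch": tips, "age": age, "before": frm, "after": to,
                    "mode": "anagenetic",
                    "polarity": _pol(frm & F, to & F),
                })
    node_age = {_tipset(n): n.age for n in tree.postorder_nodes()}
    for tips, (anc, left, right) in history.node_scenarios.items():
        for side in (left, right):
            if (anc & F) != (side & F):
                out.append({
                    "branch": tips, "age": node_age[tips], "before": anc,
                    "after": side, "mode": "cladogenetic",
                    "polarity": _pol(anc & F, side & F),
                })
    return out


def _pol(om: frozenset, dm: frozenset) -> str:
    from .transitions import _polarity_of
    return _polarity_of(om, dm)


def calls_from_truth(history: DECHistory, tree: TimeTree,
                     prob: float = 0.95) -> dict[frozenset, BranchRangeCall]:
    """Branch range calls taken from the simulated truth, with a uniform
    high certainty — for exercising the transition detector independently
    of the likelihood machinery.

    Internal branches are called by the range at the top of the branch
    (immediately after the parent's speciation, matching the
    reconstruction's marginals); terminal branches by the observed tip
    range (the bottom of the branch), which is data, not an estimate.
    """
    calls = {}
    for tips, bh in history.branches.items():
        state = bh.bottom_state if len(tips) == 1 else bh.top_state
        calls[tips] = BranchRangeCall(tips, state, prob, prob >= 0.75,
                                      {state: prob})
    root_tips = _tipset(tree.root)
    calls[root_tips] = BranchRangeCall(root_tips, history.root_range, prob,
                                       prob >= 0.75, {history.root_range: prob})
    return calls


# -- closed-loop experiments ------------------------------------------------

def parameter_recovery(n_replicates: int = 20, n_tips: int = 200,
                       d: float = 0.05, e: float = 0.02,
                       birth_rate: float = 0.25, seed: int = 0) -> dict:
    """Simulate-and-refit experiment for the DEC rates.

    Each replicate draws a Yule tree and a survival-conditioned range
    history at the true (d, e), then re-estimates both rates by maximum
    likelihood.  Returns the per-replicate estimates and the median
    relative errors |d_hat/d - 1| and |e_hat/e - 1|.
    """
    from .dec import DECModel
    space = andes_amazon_space()
    truth = DECParams(d, e)
    rows = []
    rng = np.random.default_rng(seed)
    for rep in range(n_replicates):
        tree = simulate_yule_tree(n_tips, birth_rate,
                                  seed=int(rng.integers(2**31)))
        hist = simulate_dec_history(tree, space, truth, "A",
                                    seed=int(rng.integers(2**31)),
                                    condition_on_survival=True)
        res = DECModel(tree, hist.tip_ranges, space).fit(
            seed=int(rng.integers(2**31)))
        rows.append((res.params.d, res.params.e, res.neg_loglik))
    d_err = np.median([abs(r[0] / d - 1) for r in rows])
    e_err = np.median([abs(r[1] / e - 1) for r in rows])
    return {
        "estimates": rows,
        "median_rel_error_d": float(d_err),
        "median_rel_error_e": float(e_err),
    }


def polarity_accuracy(n_histories: int = 500, n_tips: int = 8,
                      d: float = 0.03, e: float = 0.01,
                      birth_rate: float = 0.25, seed: int = 0,
                      focal=("A", "B")) -> dict:
    """Transition-caller accuracy on single-event simulated histories.

    Draws forward histories until ``n_histories`` with exactly one
    focal-membership change are collected, derives high-certainty branch
    calls from the simulated truth, runs the detector, and scores whether
    the detected polarity matches the simulated one and whether the event
    window brackets the true event age.
    """
    from .transitions import detect_transitions
    space = andes_amazon_space()
    params = DECParams(d, e)
    rng = np.random.default_rng(seed)
    n_match = n_window = n_single_call = collected = 0
    attempts = 0
    while collected < n_histories and attempts < n_histories * 500:
        attempts += 1
        tree = simulate_yule_tree(n_tips, birth_rate,
                                  seed=int(rng.integers(2**31)))
        hist = simulate_dec_history(tree, space, params, "A",
                                    seed=int(rng.integers(2**31)),
                                    condition_on_survival=True)
        truth = true_transitions(hist, tree, focal)
        if len(truth) != 1:
            continue
        collected += 1
        calls = calls_from_truth(hist, tree, prob=0.95)
        events = detect_transitions(calls, tree, focal)
        if len(events) == 1:
            n_single_call += 1
            ev = events[0]
            if ev.polarity == truth[0]["polarity"]:
                n_match += 1
            if ev.latest - 1e-9 <= truth[0]["age"] <= ev.earliest + 1e-9:
                n_window += 1
    return {
        "n_histories": collected,
        "polarity_match_rate": n_match / collected if collected else float("nan"),
        "single_event_rate": n_single_call / collected if collected else float("nan"),
        "window_bracket_rate": n_window / collected if collected else float("nan"),
    }


# -- GTR+Gamma sequences ----------------------------------------------------

def _gtr_rate_matrix(exchangeabilities, freqs) -> np.ndarray:
    s = exchangeabilities
    pi = np.asarray(freqs)
    pi = pi / pi.sum()
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    Q = np.zeros((4, 4))
    for rate, (i, j) in zip(s, pairs):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(Q))
    return Q / mean_rate


def _gamma_category_rates(alpha: float, k: int) -> np.ndarray:
    from scipy import stats as st
    if k == 1:
        return np.ones(1)
    quantiles = (np.arange(k) + 0.5) / k
    rates = st.gamma.ppf(quantiles, a=alpha, scale=1.0 / alpha)
    return rates / rates.mean()


def simulate_alignment(tree: TimeTree, config: SeqConfig = SeqConfig(),
                       seed: int = 0) -> Alignment:
    """Evolve sequences along the tree under GTR+Gamma.

    The root sequence is drawn from the stationary frequencies; each site
    carries a gamma rate multiplier (discrete categories); branch
    transition matrices are expm(Q * t * rate).
    """
    rng = np.random.default_rng(seed)
    Q = _gtr_rate_matrix(config.exchangeabilities, config.base_frequencies)
    rates = _gamma_category_rates(config.gamma_shape, config.rate_categories)
    L = config.length
    cat = rng.integers(len(rates), size=L)
    pi = np.asarray(config.base_frequencies)
    pi = pi / pi.sum()
    root_seq = rng.choice(4, size=L, p=pi)

    seqs: dict[str, np.ndarray] = {}

    def sample_children(parent_states, t):
        child = np.empty(L, dtype=np.int64)
        for c, r in enumerate(rates):
            idx = np.where(cat == c)[0]
            if idx.size == 0:
                continue
            P = linalg.expm(Q * t * r)
            P = np.clip(P, 0, None)
            P = P / P.sum(axis=1, keepdims=True)
            cdf = P.cumsum(axis=1)
            u = rng.random(idx.size)
            child[idx] = (u[:, None] > cdf[parent_states[idx]]).sum(axis=1)
        return child

    def walk(node, state):
        for ch in node.child_nodes():
            s = sample_children(state, ch.edge.length or 0.0)
            if ch.is_leaf():
                seqs[ch.taxon.label] = s
            else:
                walk(ch, s)

    walk(tree.root, root_seq)
    bases = np.array(list("ACGT"))
    out = {lab: "".join(bases[s]) for lab, s in seqs.items()}
    codon = [(i % 3) + 1 for i in range(L)] if config.annotate_codons else None
    return Alignment(out, codon)


# -- synthetic compendium ---------------------------------------------------

def simulate_compendium(config: CompendiumConfig = CompendiumConfig(),
                        seed: int = 0) -> list[TransitionRecord]:
    """Draw a synthetic transition compendium with lognormal ages.

    Configured fractions of records are emitted as symmetric "x-y" ranges
    (midpoint preserved) or as "not dated"; all draws are deterministic
    under the seed.
    """
    rng = np.random.default_rng(seed)
    records = []
    plan = [
        (AMAZON_TO_ANDES, config.n_amazon_origin, config.mu_amazon),
        (ANDES_TO_AMAZON, config.n_andes_origin, config.mu_andes),
    ]
    for pol, n, mu in plan:
        ages = rng.lognormal(mu, config.sigma, size=n)
        u = rng.random(n)
        for i, age in enumerate(ages):
            if u[i] < config.fraction_undated:
                raw = "not dated"
            elif u[i] < config.fraction_undated + config.fraction_range_ages:
                half = rng.uniform(0.05, 0.5) * age
                raw = f"{age + half:.2f}-{age - half:.2f}"
            else:
                raw = f"{age:.2f}"
            records.append(TransitionRecord(
                taxon_class="Synthetic", group="synthetic", taxa=f"taxon_{pol}_{i}",
                highest_elevation_m=2000.0, polarity=pol, age_raw=raw,
                source="simulated"))
    return records
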
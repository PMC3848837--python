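"""Dispersal-extinction-cladogenesis (DEC) ancestral range estimation.

The DEC model describes geographic range evolution on a time-calibrated
phylogeny with two anagenetic rates — dispersal ``d`` (area gains per Ma)
and extinction ``e`` (area losses per Ma) — acting along branches as a
continuous-time Markov chain over range states (subsets of a fixed area
set), plus a cladogenetic rule set acting at nodes: a single-area ancestor
passes its range to both daughters; a two-area (or wider) ancestor either
divides its range between the daughters (vicariance) or passes the whole
range to one daughter and a single constituent area to the other
(peripheral-isolate sympatry).  All cladogenetic outcomes of a given
ancestor range are weighted equally.

The likelihood is computed by Felsenstein pruning over range states, with
branch transition probabilities from the matrix exponential of the
anagenetic rate matrix.  ``DECModel.fit`` maximises the likelihood over
(log d, log e); ``DECResults.ancestral_splits`` scores every cladogenetic
split scenario at every node by the likelihood of the whole tree
conditional on that scenario, yielding relative probabilities used
downstream to call transitions.

The empty range is an absorbing state reachable by extinction from
singletons; it contributes zero likelihood at the tips, and no conditioning
on survival is applied.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import linalg, optimize

from .timetree import TimeTree

__all__ = [
    "Area",
    "RangeStateSpace",
    "DECParams",
    "SplitScenario",
    "AncestralReconstruction",
    "DECModel",
    "DECResults",
    "build_state_space",
    "build_rate_matrix",
    "branch_transition_probs",
    "tree_likelihood",
    "fit_parameters",
    "ancestral_splits",
    "read_tip_ranges",
    "andes_amazon_space",
]


@dataclass(frozen=True)
class Area:
    code: str
    name: str = ""

    def __post_init__(self):
        if len(self.code) != 1:
            raise ValueError(f"area codes are single letters, got {self.code!r}")


@dataclass(frozen=True)
class DECParams:
    """Dispersal and extinction rates, both in events per Ma (> 0)."""

    d: float
    e: float

    def __post_init__(self):
        if not (np.isfinite(self.d) and np.isfinite(self.e)):
            raise ValueError("rates must be finite")
        if self.d < 0 or self.e < 0:
            raise ValueError("rates must be non-negative")


class RangeStateSpace:
    """Allowed geographic range states over a set of areas.

    States are frozensets of area codes: the empty (absorbing) range, all
    singletons, and every adjacency-connected subset up to ``max_size``.
    Ordering is deterministic: by size, then lexicographically — the empty
    state is index 0.
    """

    def __init__(self, areas: Sequence[Area], max_size: int,
                 adjacency: Iterable[tuple[str, str]]):
        if len(areas) < 1:
            raise ValueError("need at least one area")
        if max_size < 1:
            raise ValueError("max range size must be >= 1")
        codes = [a.code for a in areas]
        if len(set(codes)) != len(codes):
            raise ValueError("area codes must be unique")
        self.areas = list(areas)
        self.codes = codes
        self.max_size = max_size
        adj: set[frozenset[str]] = set()
        for x, y in adjacency:
            if x not in codes or y not in codes:
                raise ValueError(f"adjacency references unknown area: {x}-{y}")
            if x != y:
                adj.add(frozenset((x, y)))
        self.adjacency = adj
        self.states: list[frozenset[str]] = self._enumerate_states()
        self.index = {s: i for i, s in enumerate(self.states)}
        self.nonempty = [s for s in self.states if s]

    def adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.adjacency

    def _connected(self, subset: frozenset[str]) -> bool:
        if len(subset) <= 1:
            return True
        seen = {next(iter(subset))}
        frontier = list(seen)
        while frontier:
            cur = frontier.pop()
            for other in subset - seen:
                if self.adjacent(cur, other):
                    seen.add(other)
                    frontier.append(other)
        return seen == set(subset)

    def _enumerate_states(self) -> list[frozenset[str]]:
        states = [frozenset()]
        for size in range(1, self.max_size + 1):
            for combo in itertools.combinations(sorted(self.codes), size):
                s = frozenset(combo)
                if self._connected(s):
                    states.append(s)
        states.sort(key=lambda s: (len(s), tuple(sorted(s))))
        return states

    def parse_range(self, text: str) -> frozenset[str]:
        s = frozenset(text.strip())
        if s not in self.index:
            raise KeyError(f"range {text!r} is not an allowed state")
        return s

    def format_range(self, state: frozenset[str]) -> str:
        return "".join(sorted(state)) if state else "0"

    def __len__(self):
        return len(self.states)

    def __repr__(self):
        names = ",".join(self.format_range(s) for s in self.nonempty)
        return f"<RangeStateSpace [{names}] max={self.max_size}>"


def build_state_space(areas: Sequence[Area], max_size: int,
                      adjacency: Iterable[tuple[str, str]]) -> RangeStateSpace:
    """Enumerate allowed range states (see :class:`RangeStateSpace`)."""
    return RangeStateSpace(areas, max_size, adjacency)


def andes_amazon_space() -> RangeStateSpace:
    """The study geography: Amazon (A), Andes (B), Atlantic Forest (C);
    the Amazon is the only connection among regions; ranges of at most
    two areas."""
    areas = [Area("A", "Amazon"), Area("B", "Andes"), Area("C", "Atlantic Forest")]
    return build_state_space(areas, 2, [("A", "B"), ("A", "C")])


def build_rate_matrix(space: RangeStateSpace, params: DECParams) -> np.ndarray:
    """Anagenetic rate matrix Q over range states.

    Gains: R -> R + {a} at rate d x (number of areas in R adjacent to a),
    only into allowed states.  Losses: R -> R - {a} at rate e per occupied
    area (singletons decay to the empty state).  The empty state is
    absorbing; diagonals make rows sum to zero.
    """
    n = len(space)
    Q = np.zeros((n, n))
    for i, R in enumerate(space.states):
        if not R:
            continue  # absorbing
        for a in space.codes:
            if a in R:
                continue
            target = R | {a}
            j = space.index.get(target)
            if j is None:
                continue
            k = sum(1 for b in R if space.adjacent(b, a))
            if k:
                Q[i, j] = params.d * k
        for a in R:
            target = R - {a}
            j = space.index.get(target)
            if j is not None:
                Q[i, j] += params.e
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def branch_transition_probs(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1, tiny negative entries clamped to 0."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if not np.all(np.isfinite(Q)):
        raise ValueError("rate matrix has non-finite entries")
    P = linalg.expm(Q * t)
    P[P < 0] = 0.0
    return P


def _cladogenetic_scenarios(space: RangeStateSpace):
    """Per ancestor state: list of ordered (left, right) daughter ranges,
    equally weighted.  Singletons are inherited identically; wider ranges
    split by vicariance or peripheral-isolate sympatry."""
    table: dict[frozenset, list[tuple[frozenset, frozenset]]] = {}
    for S in space.nonempty:
        if len(S) == 1:
            table[S] = [(S, S)]
            continue
        outcomes = []
        for a in sorted(S):
            sing = frozenset((a,))
            rest = S - sing
            if rest in space.index:
                outcomes.append((sing, rest))
                if len(S) > 2:  # for |S|=2 the loop over a covers both orders
                    outcomes.append((rest, sing))
            outcomes.append((sing, S))
            outcomes.append((S, sing))
        table[S] = outcomes
    return table


@dataclass(frozen=True)
class SplitScenario:
    """One cladogenetic outcome at a node, scored by the full-tree
    likelihood conditional on it."""

    node_id: int
    ancestor: frozenset
    left: frozenset
    right: frozenset
    loglik: float
    rel_prob: float
    retained: bool = True


@dataclass
class AncestralReconstruction:
    """Per-node split scenarios and per-daughter-branch range marginals."""

    params: DECParams
    neg_loglik: float
    window: float
    floor: float
    node_scenarios: dict[int, list[SplitScenario]]
    branch_marginals: dict[int, dict[frozenset, float]]
    subthreshold: dict[int, set[frozenset]]
    node_tips: dict[int, tuple[str, ...]]
    space: RangeStateSpace

    def best_range(self, branch_id: int) -> tuple[frozenset, float]:
        marg = self.branch_marginals[branch_id]
        best = max(marg, key=lambda s: (marg[s], tuple(sorted(s))))
        return best, marg[best]

    def scenario_table(self):
        """Rows (node_id, left, right, lnL, relP, retained) for export."""
        rows = []
        fmt = self.space.format_range
        for nid in sorted(self.node_scenarios):
            for sc in self.node_scenarios[nid]:
                rows.append((nid, fmt(sc.ancestor), fmt(sc.left), fmt(sc.right),
                             sc.loglik, sc.rel_prob, sc.retained))
        return rows


class _TreeIndex:
    """Flat postorder arrays for a bifurcating TimeTree."""

    def __init__(self, tree: TimeTree):
        if not tree.is_bifurcating():
            raise ValueError(
                "tree contains polytomies; the DEC cladogenetic rule set "
                "requires a fully bifurcating tree — resolve polytomies first"
            )
        self.nodes = list(tree.postorder_nodes())
        self.id_of = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = []
        self.blen = []
        self.labels = []
        for n in self.nodes:
            kids = n.child_nodes()
            self.children.append(tuple(self.id_of[id(c)] for c in kids))
            self.blen.append(n.edge.length or 0.0)
            self.labels.append(n.taxon.label if n.taxon else None)
        self.root = len(self.nodes) - 1
        self.tips_below = [None] * len(self.nodes)
        for i, n in enumerate(self.nodes):
            if not self.children[i]:
                self.tips_below[i] = (self.labels[i],)
            else:
                acc = []
                for c in self.children[i]:
                    acc.extend(self.tips_below[c])
                self.tips_below[i] = tuple(acc)


class _Propagator:
    """Branch transition probabilities via eigendecomposition of Q, with a
    dense expm fallback when Q is defective."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            # reject near-defective decompositions
            if np.linalg.cond(V) < 1e10:
                self.w, self.V, self.Vinv = w, V, Vinv
            else:
                self.w = None
        except np.linalg.LinAlgError:
            self.w = None

    def __call__(self, t: float) -> np.ndarray:
        if self.w is None:
            return branch_transition_probs(self.Q, t)
        P = (self.V * np.exp(self.w * t)) @ self.Vinv
        P = np.real(P)
        P[P < 0] = 0.0
        return P


class DECModel:
    """DEC model for a time tree and tip range data.

    Parameters
    ----------
    tree : TimeTree
        Strictly bifurcating ultrametric tree with branch lengths in Ma.
    tip_ranges : mapping of tip label -> range
        Ranges as frozensets of area codes or strings like ``"AB"``.
    space : RangeStateSpace, optional
        Defaults to the Amazon-hub three-area geography.
    root_constraint : range, optional
        Restrict the root ancestor to one allowed state.
    """

    def __init__(self, tree: TimeTree, tip_ranges: Mapping[str, object],
                 space: Optional[RangeStateSpace] = None,
                 root_constraint=None):
        self.tree = tree
        self.space = space if space is not None else andes_amazon_space()
        self.index = _TreeIndex(tree)
        self.scenarios = _cladogenetic_scenarios(self.space)
        # flatten scenario table to index arrays per ancestor state
        self._scen = {}
        for S, outs in self.scenarios.items():
            w = 1.0 / len(outs)
            self._scen[self.space.index[S]] = [
                (self.space.index[l], self.space.index[r], w) for l, r in outs
            ]
        self.tip_state = {}
        for i, lab in enumerate(self.index.labels):
            if lab is None:
                continue
            if lab not in tip_ranges:
                raise KeyError(f"tip {lab!r} has no range coding")
            rng = tip_ranges[lab]
            if isinstance(rng, str):
                rng = self.space.parse_range(rng)
            if rng not in self.space.index or not rng:
                raise KeyError(f"tip {lab!r} range is not an allowed non-empty state")
            self.tip_state[i] = self.space.index[rng]
        if root_constraint is not None and isinstance(root_constraint, str):
            root_constraint = self.space.parse_range(root_constraint)
        if root_constraint is not None and root_constraint not in self.space.index:
            raise KeyError("root constraint is not an allowed state")
        self.root_constraint = root_constraint

    # -- likelihood --------------------------------------------------------

    def _root_mask(self) -> np.ndarray:
        n = len(self.space)
        mask = np.zeros(n)
        if self.root_constraint is not None:
            mask[self.space.index[self.root_constraint]] = 1.0
        else:
            for s in self.space.nonempty:
                mask[self.space.index[s]] = 1.0
        return mask

    def _pruning(self, params: DECParams):
        """Postorder conditional likelihoods with per-node rescaling.

        Returns (L, logscale, up) where L[i] is the scaled conditional
        vector at node i (ancestor state just before cladogenesis; tips are
        indicators), logscale[i] the accumulated log scale below i, and
        up[i] the branch-propagated vector at the top of i's branch.
        """
        idx = self.index
        n_states = len(self.space)
        Q = build_rate_matrix(self.space, params)
        prop = _Propagator(Q)
        L = [None] * len(idx.nodes)
        up = [None] * len(idx.nodes)
        logscale = np.zeros(len(idx.nodes))
        for i in range(len(idx.nodes)):
            kids = idx.children[i]
            if not kids:
                v = np.zeros(n_states)
                v[self.tip_state[i]] = 1.0
                L[i] = v
            else:
                c1, c2 = kids
                v = np.zeros(n_states)
                for S, outs in self._scen.items():
                    acc = 0.0
                    u1, u2 = up[c1], up[c2]
                    for l, r, w in outs:
                        acc += w * u1[l] * u2[r]
                    v[S] = acc
                logscale[i] = logscale[c1] + logscale[c2]
                m = v.max()
                if m <= 0:
                    # data impossible under params (can happen at d=0)
                    L[i] = v
                else:
                    v = v / m
                    logscale[i] += math.log(m)
                    L[i] = v
            if i != idx.root:
                up[i] = prop(idx.blen[i]) @ L[i]
        return L, logscale, up, prop

    def loglike(self, params: DECParams) -> float:
        L, logscale, _, _ = self._pruning(params)
        mask = self._root_mask()
        tot = float(mask @ L[self.index.root])
        if tot <= 0:
            return -np.inf
        return math.log(tot) + logscale[self.index.root]

    def neg_loglik(self, params: DECParams) -> float:
        return -self.loglike(params)

    # -- fitting -----------------------------------------------------------

    def fit(self, starts: Optional[Sequence[tuple[float, float]]] = None,
            tol: float = 1e-8, seed: int = 0) -> "DECResults":
        """Maximise the likelihood over (log d, log e), multi-start
        Nelder-Mead.  Default starts are drawn from a jittered
        {0.001, 0.01, 0.1} grid."""
        rng = np.random.default_rng(seed)
        if starts is None:
            grid = [(0.01, 0.01), (0.1, 0.01), (0.001, 0.01),
                    (0.01, 0.001), (0.1, 0.1)]
            starts = [(d * math.exp(rng.normal(0, 0.1)),
                       e * math.exp(rng.normal(0, 0.1))) for d, e in grid]

        def objective(x):
            d, e = math.exp(x[0]), math.exp(x[1])
            if d > 1e3 or e > 1e3:
                return np.inf
            val = self.neg_loglik(DECParams(d, e))
            return val if np.isfinite(val) else 1e10

        best = None
        reports = []
        for d0, e0 in starts:
            res = optimize.minimize(
                objective, [math.log(d0), math.log(e0)],
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": tol, "maxiter": 500},
            )
            reports.append(res)
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"optimizer failed to converge; best so far: {best}")
        params = DECParams(math.exp(best.x[0]), math.exp(best.x[1]))
        return DECResults(
            model=self,
            params=params,
            neg_loglik=float(best.fun),
            converged=bool(best.success),
            n_starts=len(starts),
            optimizer_report=reports,
        )

    # -- ancestral reconstruction ------------------------------------------

    def ancestral_splits(self, params: DECParams, window: float = 2.0,
                         floor: float = 0.1) -> AncestralReconstruction:
        """Score every cladogenetic scenario at every internal node.

        A scenario's relative probability is the likelihood of the tree
        conditional on that split divided by the sum over all scenarios at
        the node (these sum to 1 per node).  Scenarios within ``window``
        log-likelihood units of the node's best are flagged retained.
        Per-daughter-branch range marginals sum relative probabilities over
        scenarios sharing the daughter range; marginals below ``floor`` are
        reported but flagged sub-threshold.
        """
        idx = self.index
        n_states = len(self.space)
        L, logscale, up, prop = self._pruning(params)
        mask = self._root_mask()
        tot_root = float(mask @ L[idx.root])
        if tot_root <= 0:
            raise ValueError("data have zero likelihood under these parameters")
        loglik = math.log(tot_root) + logscale[idx.root]

        # outside pass: G[i][S] = d L_root / d L_i[S], scaled per node
        G = [None] * len(idx.nodes)
        G[idx.root] = mask.copy()
        order = list(range(len(idx.nodes) - 1, -1, -1))  # preorder on our ids
        for i in order:
            kids = idx.children[i]
            if not kids:
                continue
            c1, c2 = kids
            g1 = np.zeros(n_states)
            g2 = np.zeros(n_states)
            u1, u2 = up[c1], up[c2]
            gi = G[i]
            for S, outs in self._scen.items():
                gS = gi[S]
                if gS == 0.0:
                    continue
                for l, r, w in outs:
                    g1[l] += gS * w * u2[r]
                    g2[r] += gS * w * u1[l]
            for c, g in ((c1, g1), (c2, g2)):
                Gc = g @ prop(idx.blen[c])
                m = Gc.max()
                G[c] = Gc / m if m > 0 else Gc
        # scenario joints per node
        node_scenarios: dict[int, list[SplitScenario]] = {}
        branch_marginals: dict[int, dict[frozenset, float]] = {}
        subthr: dict[int, set[frozenset]] = {}
        states = self.space.states
        for i in range(len(idx.nodes)):
            kids = idx.children[i]
            if not kids:
                continue
            c1, c2 = kids
            u1, u2 = up[c1], up[c2]
            gi = G[i]
            joints = []
            for S, outs in self._scen.items():
                for l, r, w in outs:
                    joints.append((S, l, r, gi[S] * w * u1[l] * u2[r]))
            total = sum(j for *_, j in joints)
            scens = []
            m1: dict[frozenset, float] = {}
            m2: dict[frozenset, float] = {}
            for S, l, r, j in joints:
                p = j / total if total > 0 else 0.0
                lnl = (loglik + math.log(p)) if p > 0 else -np.inf
                scens.append(SplitScenario(
                    node_id=i, ancestor=states[S], left=states[l],
                    right=states[r], loglik=lnl, rel_prob=p))
                m1[states[l]] = m1.get(states[l], 0.0) + p
                m2[states[r]] = m2.get(states[r], 0.0) + p
            best_lnl = max(sc.loglik for sc in scens)
            scens = [
                SplitScenario(sc.node_id, sc.ancestor, sc.left, sc.right,
                              sc.loglik, sc.rel_prob,
                              retained=sc.loglik >= best_lnl - window)
                for sc in sorted(scens, key=lambda s: -s.rel_prob)
            ]
            node_scenarios[i] = scens
            branch_marginals[c1] = m1
            branch_marginals[c2] = m2
            for c, m in ((c1, m1), (c2, m2)):
                subthr[c] = {s for s, p in m.items() if p < floor}
        return AncestralReconstruction(
            params=params, neg_loglik=-loglik, window=window, floor=floor,
            node_scenarios=node_scenarios, branch_marginals=branch_marginals,
            subthreshold=subthr,
            node_tips={i: idx.tips_below[i] for i in range(len(idx.nodes))},
            space=self.space,
        )


@dataclass
class DECResults:
    """Fitted DEC rates and optimum, with access to ancestral splits."""

    model: DECModel
    params: DECParams
    neg_loglik: float
    converged: bool
    n_starts: int
    optimizer_report: list = field(repr=False, default_factory=list)

    def ancestral_splits(self, window: float = 2.0, floor: float = 0.1):
        return self.model.ancestral_splits(self.params, window=window, floor=floor)

    def summary(self) -> str:
        space = self.model.space
        lines = [
            "DEC model fit",
            "=" * 46,
            f"tips:                {self.model.tree.n_tips}",
            f"areas:               {','.join(space.codes)} (max range {space.max_size})",
            f"states:              {len(space) - 1} non-empty",
            f"dispersal d:         {self.params.d:.6g} /Ma",
            f"extinction e:        {self.params.e:.6g} /Ma",
            f"-lnL:                {self.neg_loglik:.4f}",
            f"converged:           {self.converged} ({self.n_starts} starts)",
        ]
        if self.model.root_constraint is not None:
            lines.append(
                f"root constraint:     {space.format_range(self.model.root_constraint)}")
        return "\n".join(lines)


# -- functional wrappers (module-level operations) --------------------------

def tree_likelihood(tree: TimeTree, tip_ranges, params: DECParams,
                    space: Optional[RangeStateSpace] = None,
                    root_constraint=None) -> float:
    """Negative log-likelihood of tip ranges under DEC on the tree."""
    return DECModel(tree, tip_ranges, space, root_constraint).neg_loglik(params)


def fit_parameters(tree: TimeTree, tip_ranges,
                   space: Optional[RangeStateSpace] = None,
                   root_constraint=None, **kwargs) -> DECResults:
    return DECModel(tree, tip_ranges, space, root_constraint).fit(**kwargs)


def ancestral_splits(tree: TimeTree, tip_ranges, params: DECParams,
                     space: Optional[RangeStateSpace] = None,
                     root_constraint=None, window: float = 2.0,
                     floor: float = 0.1) -> AncestralReconstruction:
    model = DECModel(tree, tip_ranges, space, root_constraint)
    return model.ancestral_splits(params, window=window, floor=floor)


def read_tip_ranges(path) -> dict[str, str]:
    """Read a two-column TSV ``tip<TAB>areas`` (areas as concatenated codes)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tip, rng = line.split("\t")
            out[tip] = rng
    return out
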
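"""Calling biogeographic transitions from ancestral-range reconstructions.

A reconstruction gives, for every branch, the relative probability that the
lineage occupied each range immediately after the speciation event at the
branch's origin.  This module turns those per-branch range calls into
discrete transition events between two focal regions (here Amazon, A, and
Andes, B): the event's polarity (which region the ancestor occupied and
which the descendant moved into), how far rootward the origin had to be
traced before a call was certain (depth i/ii/iii), the time window
bracketing the change, and a coarse age typology:

* type 1 — older than 7.5 Ma (historically tied to Andean uplift),
* type 2 — 2.5 to 7.5 Ma (regression of the Pebas wetland system),
* type 3 — 2.5 Ma or younger (Plio-Pleistocene climate cycling), either
  polarity.

A call is *certain* when its best range carries probability at or above the
threshold (default 0.75).  Polarity is taken from the nearest certain
ancestor call, walking at most three branches rootward; if every candidate
range of an uncertain ancestor implies the same polarity the call is
promoted with a note, otherwise the polarity is reported uncertain with the
candidate set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .dec import AncestralReconstruction
from .timetree import TimeTree

__all__ = [
    "BranchRangeCall",
    "TransitionEvent",
    "TransitionTypeBin",
    "TYPE_BINS",
    "classify_branch_ranges",
    "detect_transitions",
    "assign_type",
]

CERTAINTY_THRESHOLD = 0.75
MAX_DEPTH = 3
_DEPTH_LABELS = {1: "i", 2: "ii", 3: "iii"}


@dataclass(frozen=True)
class BranchRangeCall:
    """Best range call for one branch (keyed by its subtended tip set)."""

    branch: frozenset
    best_range: frozenset
    prob: float
    certain: bool
    marginals: Mapping[frozenset, float] = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class TransitionTypeBin:
    label: str
    lower: float  # exclusive
    upper: float  # inclusive
    polarity_note: str

    def contains(self, age: float) -> bool:
        return self.lower < age <= self.upper or (self.lower == 0 and age == 0)

    @property
    def width(self) -> Optional[float]:
        return None if math.isinf(self.upper) else self.upper - self.lower


#: Non-overlapping bins partitioning [0, inf): ages fall in exactly one.
TYPE_BINS = (
    TransitionTypeBin("3", 0.0, 2.5, "either polarity"),
    TransitionTypeBin("2", 2.5, 7.5, "Andean origin expected"),
    TransitionTypeBin("1", 7.5, math.inf, "Amazonian origin expected"),
)


@dataclass
class TransitionEvent:
    """One inferred focal-region transition."""

    label: str
    clade: tuple[str, ...]
    polarity: str  # e.g. "A->B", or "uncertain"
    depth: Optional[str]  # "i" | "ii" | "iii" | None when polarity uncertain
    earliest: float  # stem-side bound (Ma)
    latest: float  # crown-side bound (Ma)
    kind: str  # "shift" | "expansion" | "contraction"
    candidates: tuple[str, ...] = ()
    note: str = ""
    support: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.earliest < self.latest - 1e-9:
            raise ValueError(
                f"event window inverted: earliest {self.earliest} < latest {self.latest}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.earliest + self.latest)


def classify_branch_ranges(
    recon: AncestralReconstruction,
    threshold: float = CERTAINTY_THRESHOLD,
) -> dict[frozenset, BranchRangeCall]:
    """One call per branch from the reconstruction's marginals.

    Branches are keyed by the frozenset of tip labels they subtend.  The
    root node contributes a pseudo-branch (all tips) whose call is the
    marginal over root ancestor states, so that transitions on the root's
    daughter branches have a reference.  Ties on probability break by
    state-space order (lexicographic range string).
    """
    calls: dict[frozenset, BranchRangeCall] = {}
    tipsets = {nid: frozenset(tips) for nid, tips in recon.node_tips.items()}
    for nid, marg in recon.branch_marginals.items():
        key = tipsets[nid]
        best = max(sorted(marg, key=lambda s: tuple(sorted(s))),
                   key=lambda s: marg[s])
        p = marg[best]
        calls[key] = BranchRangeCall(key, best, p, p >= threshold, dict(marg))
    # root pseudo-branch: marginal over ancestor states of the root node
    root_id = max(recon.node_scenarios)
    root_marg: dict[frozenset, float] = {}
    for sc in recon.node_scenarios[root_id]:
        root_marg[sc.ancestor] = root_marg.get(sc.ancestor, 0.0) + sc.rel_prob
    key = tipsets[root_id]
    best = max(sorted(root_marg, key=lambda s: tuple(sorted(s))),
               key=lambda s: root_marg[s])
    p = root_marg[best]
    calls[key] = BranchRangeCall(key, best, p, p >= threshold, root_marg)
    return calls


def _membership(rng: frozenset, focal: tuple[str, str]) -> frozenset:
    return rng & frozenset(focal)


def _polarity_of(origin_m: frozenset, dest_m: frozenset) -> str:
    gained = dest_m - origin_m
    lost = origin_m - dest_m
    origin = lost if lost else origin_m
    dest = gained if gained else dest_m
    fmt = lambda s: "/".join(sorted(s)) if s else "none"
    return f"{fmt(origin)}->{fmt(dest)}"


def detect_transitions(
    calls: Mapping[frozenset, BranchRangeCall],
    tree: TimeTree,
    focal_regions: tuple[str, str] = ("A", "B"),
) -> list[TransitionEvent]:
    """Emit one event wherever a branch's called range differs from its
    parent branch's called range in focal-region membership.

    When both daughters of a node show the same membership change relative
    to their parent branch, the change is placed on the parent branch and a
    single event is emitted for the whole daughter clade (an anagenetic
    change along the branch); otherwise the change is cladogenetic and tied
    to the differing daughter.  Polarity comes from the nearest certain
    ancestor call, walking rootward at most three branches; the window runs
    from the stem age of the earliest branch on which the change could have
    begun down to the descendant clade's crown age.
    """
    focal = tuple(focal_regions)
    # index nodes by tipset
    nodes = {}
    for node in tree.postorder_nodes():
        tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
        nodes[tips] = node
    missing = [k for k in nodes if k not in calls]
    if missing:
        raise KeyError(f"calls missing for {len(missing)} branch(es)")

    def parent_key(key):
        node = nodes[key]
        if node.parent_node is None:
            return None
        return frozenset(lf.taxon.label for lf in node.parent_node.leaf_iter())

    # raw per-branch differences
    diffs = {}
    for key, node in nodes.items():
        pk = parent_key(key)
        if pk is None:
            continue
        mb = _membership(calls[key].best_range, focal)
        mp = _membership(calls[pk].best_range, focal)
        if mb != mp:
            diffs[key] = (mp, mb)

    # merge sibling pairs showing the identical change -> anagenetic on parent
    events_raw = []  # (descendant_key, origin_branch_key, mp, mb, kind_flag)
    consumed = set()
    for key in sorted(diffs, key=lambda k: (len(k), tuple(sorted(k)))):
        if key in consumed:
            continue
        node = nodes[key]
        pk = parent_key(key)
        siblings = [
            frozenset(lf.taxon.label for lf in sib.leaf_iter())
            for sib in node.parent_node.child_nodes()
            if frozenset(lf.taxon.label for lf in sib.leaf_iter()) != key
        ]
        mp, mb = diffs[key]
        merged = False
        for sk in siblings:
            if sk in diffs and diffs[sk] == (mp, mb) and sk not in consumed:
                # same change on both daughters: anagenetic along parent branch
                events_raw.append((pk, pk, mp, mb, "anagenetic"))
                consumed.add(key)
                consumed.add(sk)
                merged = True
                break
        if not merged:
            events_raw.append((key, pk, mp, mb, "cladogenetic"))
            consumed.add(key)

    events = []
    for i, (desc_key, origin_key, mp, mb, mode) in enumerate(events_raw):
        desc_node = nodes[desc_key]
        crown = desc_node.age
        if mb > mp:
            kind = "expansion"
        elif mb < mp:
            kind = "contraction"
        else:
            kind = "shift"
        # walk rootward for a certain origin call
        depth = None
        origin_call = None
        walk_key = origin_key if mode == "cladogenetic" else parent_key(origin_key)
        # for a cladogenetic change the stem branch is the parent branch of
        # the descendant; for an anagenetic change it is the branch above it
        chain = []
        k = walk_key
        for step in range(1, MAX_DEPTH + 1):
            if k is None:
                break
            chain.append((step, k))
            if calls[k].certain:
                depth = step
                origin_call = calls[k]
                break
            k = parent_key(k)
        support = {
            f"[{_DEPTH_LABELS[s]}]": {
                "".join(sorted(r)): round(p, 4)
                for r, p in sorted(calls[key_].marginals.items(),
                                   key=lambda kv: -kv[1])
            }
            for s, key_ in chain
        }
        note = ""
        if origin_call is not None:
            om = _membership(origin_call.best_range, focal)
            polarity = _polarity_of(om if om else mp, mb)
            candidates = ()
        else:
            # uncertain all the way: do all candidate ranges of the nearest
            # ancestor imply the same polarity?
            ref = calls[walk_key] if walk_key is not None else None
            cand_pols = set()
            implies_no_change = False
            if ref is not None:
                for r, p in ref.marginals.items():
                    if p <= 0:
                        continue
                    om = _membership(r, focal)
                    if om == mb:
                        # this candidate would mean no transition here at all
                        implies_no_change = True
                    else:
                        cand_pols.add(_polarity_of(om if om else mp, mb))
            if len(cand_pols) == 1 and not implies_no_change:
                polarity = cand_pols.pop()
                depth = 1
                note = "all candidate ancestor ranges imply this polarity"
                candidates = ()
            else:
                polarity = "uncertain"
                candidates = tuple(sorted(cand_pols))
        # window: stem age of the earliest branch where the change could
        # have begun
        if depth is not None and origin_call is not None:
            top_key = chain[depth - 1][1]
        elif chain:
            top_key = chain[-1][1]
        else:
            top_key = origin_key
        top_node = nodes[top_key]
        earliest = (top_node.parent_node.age
                    if top_node.parent_node is not None else top_node.age)
        events.append(TransitionEvent(
            label=f"T{i + 1}",
            clade=tuple(sorted(desc_key)),
            polarity=polarity,
            depth=_DEPTH_LABELS.get(depth),
            earliest=earliest,
            latest=crown,
            kind=kind,
            candidates=candidates,
            note=note,
            support=support,
        ))
    return events


def assign_type(event_or_age, age: Optional[float] = None) -> TransitionTypeBin:
    """Map a transition age (Ma) to its type bin.

    Accepts either an age, or a :class:`TransitionEvent` (whose window
    midpoint is used by default, or ``age`` when given).  Bins are
    inclusive above: 2.5 Ma is type 3 and 7.5 Ma is type 2.
    """
    if isinstance(event_or_age, TransitionEvent):
        a = event_or_age.midpoint if age is None else age
    else:
        a = float(event_or_age)
    if a < 0:
        raise ValueError(f"age must be >= 0, got {a}")
    for b in TYPE_BINS:
        if b.contains(a):
            return b
    raise AssertionError("type bins failed to cover a nonnegative age")
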
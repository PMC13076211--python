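"""The decoder's state space: eukaryotic gene grammar as a transition system.

Super-states are {intergenic, UTR, CDS, intron}.  CDS decomposes into 10
substates by phase and codon kind: three start-codon positions (A, T, G),
three regular codon positions, and a four-state stop-codon automaton
(T, TA, TG, final base).  Introns decompose into 60 substates: 2 (start /
continuation) x 3 splice-motif classes (GT-AG, GC-AG, other) x 10 outer
states, where the outer state is the interrupted context the intron must
restore -- the UTR, or one of the nine CDS substates an intron can resume
into (every CDS substate except the first start-codon base; an intron
immediately before the A of ATG is a 5'UTR intron).  Carrying the outer
state through the intron is what preserves codon phase across splicing.

Transitions either require no motif or name one: ATG at a start codon, GT/GC
(or anything, for the "other" class) at a donor, AG at an acceptor, and
TAA/TAG/TGA spelled by the stop automaton.  Motif requirements are expressed
as per-state base requirements plus per-transition checks at small offsets
relative to the entered base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .encoding import CDS, IG, INTRON, UTR

#: (name, phase label, required base(s) or None) for the 10 CDS substates.
CDS_SUBSTATES = (
    ("start0", 0, "A"),
    ("start1", 2, "T"),
    ("start2", 1, "G"),
    ("reg0", 0, None),
    ("reg1", 2, None),
    ("reg2", 1, None),
    ("stopT", 0, "T"),
    ("stopTA", 2, "A"),
    ("stopTG", 2, "G"),
    ("stopX", 1, None),  # final stop base; allowed base depends on predecessor
)

#: default intron motif classes: (name, donor dimer or None, acceptor dimer or
#: None, penalty key).  The canonical GT-AG class costs nothing; the others
#: carry configurable penalties (infinite by default = canonical-only).
DEFAULT_MOTIF_CLASSES = (
    ("GT_AG", "GT", "AG", "gt_ag"),
    ("GC_AG", "GC", "AG", "gc_ag"),
    ("OTHER", None, None, "other"),
)

#: CDS-internal successor pairs (predecessor -> resume target); an intron may
#: sit on any of these edges, and the resume target is its outer state.
CDS_EDGES = (
    ("start0", "start1"),
    ("start1", "start2"),
    ("start2", "reg0"),
    ("start2", "stopT"),
    ("reg0", "reg1"),
    ("reg1", "reg2"),
    ("reg2", "reg0"),
    ("reg2", "stopT"),
    ("stopT", "stopTA"),
    ("stopT", "stopTG"),
    ("stopTA", "stopX"),
    ("stopTG", "stopX"),
)

#: resume targets reachable through an intron (9 CDS substates; start0 is
#: reached via the UTR outer state instead).
CDS_OUTER = tuple(n for n, _, _ in CDS_SUBSTATES if n != "start0")


@dataclass(frozen=True)
class State:
    index: int
    name: str
    super_class: int  # channel in the genic-class track
    phase: int | None  # phase label for CDS states, else None
    base_allowed: str | None  # required base(s) at this state's position
    codon_kind: str | None = None  # start / regular / stop for CDS states
    intron_entry: str | None = None  # "start" / "cont" for intron states
    motif_class: str | None = None
    outer: str | None = None


@dataclass(frozen=True)
class Transition:
    frm: int
    to: int
    #: checks: (offset relative to the entered base, allowed bases); all must
    #: hold for the transition's motif to count as matched.
    checks: tuple[tuple[int, str], ...] = ()
    #: penalty key looked up in PenaltyParams.motif_penalties ("" = free)
    penalty_key: str = ""


@dataclass(frozen=True)
class StateSpaceConfig:
    motif_classes: tuple = DEFAULT_MOTIF_CLASSES
    include_utr: bool = True
    #: when True (the default grammar) the substate counts are asserted:
    #: exactly 10 CDS and 60 intron substates.
    standard: bool = True


@dataclass
class HmmStateSpace:
    states: list[State]
    transitions: list[Transition]
    by_name: dict[str, State] = field(default_factory=dict)

    def __post_init__(self):
        self.by_name = {s.name: s for s in self.states}

    @property
    def n_states(self) -> int:
        return len(self.states)

    def substates(self, super_class: int) -> list[State]:
        return [s for s in self.states if s.super_class == super_class]

    def successors(self, idx: int) -> list[Transition]:
        return [t for t in self.transitions if t.frm == idx]


def build_state_space(cfg: StateSpaceConfig = StateSpaceConfig()) -> HmmStateSpace:
    """Enumerate states and legal transitions for the decoding grammar.

    Raises :class:`ValueError` when a standard config cannot yield the 10/60
    substate decomposition (e.g. a motif-class count other than three).
    """
    n_outer = len(CDS_OUTER) + (1 if cfg.include_utr else 0)
    if cfg.standard:
        if not cfg.include_utr:
            raise ValueError("standard grammar requires the UTR state")
        n_intron = 2 * len(cfg.motif_classes) * n_outer
        if n_intron != 60:
            raise ValueError(
                f"standard grammar requires 60 intron substates, config yields "
                f"{n_intron} (2 x {len(cfg.motif_classes)} motif classes x "
                f"{n_outer} outer states)"
            )

    states: list[State] = []

    def add(name, super_class, phase=None, base=None, **kw) -> State:
        st = State(len(states), name, super_class, phase, base, **kw)
        states.append(st)
        return st

    add("IG", IG)
    if cfg.include_utr:
        add("UTR", UTR)
    for name, phase, base in CDS_SUBSTATES:
        kind = "start" if name.startswith("start") else (
            "stop" if name.startswith("stop") else "regular"
        )
        add(name, CDS, phase, base, codon_kind=kind)
    outers = (("UTR",) if cfg.include_utr else ()) + CDS_OUTER
    for mname, donor, _acc, _key in cfg.motif_classes:
        for outer in outers:
            for entry in ("start", "cont"):
                add(
                    f"i_{entry}[{mname}|{outer}]",
                    INTRON,
                    base=donor[0] if (entry == "start" and donor) else None,
                    intron_entry=entry,
                    motif_class=mname,
                    outer=outer,
                )

    idx = {s.name: s.index for s in states}
    transitions: list[Transition] = []

    def t(frm, to, checks=(), key=""):
        transitions.append(Transition(idx[frm], idx[to], tuple(checks), key))

    t("IG", "IG")
    t("IG", "start0")
    if cfg.include_utr:
        t("IG", "UTR")
        t("UTR", "UTR")
        t("UTR", "start0")
        t("UTR", "IG")
        t("stopX", "UTR")
    t("stopX", "IG")
    for frm, to in CDS_EDGES:
        t(frm, to)
    # the final stop base: TAA/TAG after TA, TGA after TG
    transitions = [
        tr
        for tr in transitions
        if not (states[tr.frm].name in ("stopTA", "stopTG") and states[tr.to].name == "stopX")
    ]
    t("stopTA", "stopX", checks=[(0, "AG")])
    t("stopTG", "stopX", checks=[(0, "A")])

    for mname, donor, acceptor, key in cfg.motif_classes:
        donor2 = [(0, donor[1])] if donor else []
        acc2 = [(-2, acceptor[0]), (-1, acceptor[1])] if acceptor else []
        for outer in outers:
            istart = f"i_start[{mname}|{outer}]"
            icont = f"i_cont[{mname}|{outer}]"
            t(istart, icont, checks=donor2)
            t(icont, icont)
            if outer == "UTR":
                t("UTR", istart, key=key)
                t(icont, "UTR", checks=acc2)
                t(icont, "start0", checks=acc2)
            else:
                for frm, to in CDS_EDGES:
                    if to == outer:
                        t(frm, istart, key=key)
                t(icont, outer, checks=acc2)

    return HmmStateSpace(states, transitions)


def build_reduced_state_space() -> HmmStateSpace:
    """A small UTR-less, canonical-intron-only grammar.

    Used for exhaustive path enumeration in tests and benchmarks, where the
    full 72-state space would make brute force intractable; not a standard
    decoding configuration.
    """
    return build_state_space(
        StateSpaceConfig(
            motif_classes=(DEFAULT_MOTIF_CLASSES[0],),
            include_utr=False,
            standard=False,
        )
    )
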
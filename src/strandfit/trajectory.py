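"""Per-frame statistics over hydrogen-bond trajectories.

Turns recorded bond lists into the quantities used to compare predator
strands: per-pair MCO/TMO time series, pooled probability histograms,
ensemble-averaged time series, binding-event lifetimes, multi-strand complex
detection (connected components of the strand-contact graph) and
intra-strand self-folding summaries.

Frame-level MCO counts only strict antiparallel runs — bonds
``(i+k on a) <-> (j-k on b)`` in each strand's 5'->3' local indexing — so it
is bounded above by the sequence-level omega of the pair whenever the bonds
are canonical.  Any bond contributes to TMO.
"""
from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError
from .oxdna import HBFrame, Topology

# ---------------------------------------------------------------------------
# Per-frame pair overlap


def _antiparallel_mco(pairs: set[tuple[int, int]]) -> int:
    """Longest chain (i+k, j-k) in a set of (local_a, local_b) bonds."""
    best = 0
    for i, j in pairs:
        if (i - 1, j + 1) in pairs:
            continue  # not a chain start
        k = 1
        while (i + k, j - k) in pairs:
            k += 1
        if k > best:
            best = k
    return best


def frame_pair_overlap(
    frame: HBFrame, topo: Topology, a: str, b: str
) -> tuple[int, int]:
    """(MCO, TMO) between strands ``a`` and ``b`` in one frame.

    TMO is the number of bonds joining the two strands; MCO is the longest
    antiparallel run among them.  Bonds of either strand with third strands
    are ignored.
    """
    if a == b:
        raise InputError("frame_pair_overlap needs two distinct strands")
    sid_a = topo.strand_id_of_name(a)
    sid_b = topo.strand_id_of_name(b)
    local_pairs: set[tuple[int, int]] = set()
    for i, j in frame.pairs:
        si, sj = topo.strand_of[i], topo.strand_of[j]
        if (si, sj) == (sid_a, sid_b):
            local_pairs.add((topo.local_index[i], topo.local_index[j]))
        elif (si, sj) == (sid_b, sid_a):
            local_pairs.add((topo.local_index[j], topo.local_index[i]))
    tmo = len(local_pairs)
    mco = _antiparallel_mco(local_pairs)
    return mco, tmo


@dataclass
class PairTrace:
    """Per-pair (MCO, TMO) time series over one simulation run."""

    pair: tuple[str, str]
    steps: np.ndarray
    mco: np.ndarray
    tmo: np.ndarray

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=np.int64)
        self.mco = np.asarray(self.mco, dtype=np.int64)
        self.tmo = np.asarray(self.tmo, dtype=np.int64)
        if not (len(self.steps) == len(self.mco) == len(self.tmo)):
            raise InputError("steps/mco/tmo must have equal lengths")
        if np.any(self.tmo < self.mco):
            raise InputError("TMO < MCO is impossible; corrupt trace")

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def bound_fraction(self) -> float:
        """Fraction of frames with at least one bond (TMO >= 1)."""
        return float(np.mean(self.tmo >= 1)) if len(self) else 0.0

    def record_interval(self) -> int:
        """Step spacing of the trace (requires a uniform grid)."""
        if len(self.steps) < 2:
            return 1
        diffs = np.diff(self.steps)
        if np.any(diffs != diffs[0]) or diffs[0] <= 0:
            raise InputError("trace step grid is not uniform")
        return int(diffs[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": self.steps, "mco": self.mco, "tmo": self.tmo})


def build_traces(
    topo: Topology,
    frames: Iterable[HBFrame],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], PairTrace]:
    """One :class:`PairTrace` per strand pair over a frame sequence.

    ``pairs`` defaults to every unordered pair of distinct strands.
    """
    names = [topo.names[sid] for sid in sorted(topo.names)]
    if pairs is None:
        pairs = [(a, b) for k, a in enumerate(names) for b in names[k + 1:]]
    steps: list[int] = []
    series: dict[tuple[str, str], tuple[list[int], list[int]]] = {
        p: ([], []) for p in pairs}
    for frame in frames:
        steps.append(frame.step)
        for p in pairs:
            mco, tmo = frame_pair_overlap(frame, topo, *p)
            series[p][0].append(mco)
            series[p][1].append(tmo)
    return {
        p: PairTrace(p, np.array(steps), np.array(m), np.array(t))
        for p, (m, t) in series.items()
    }


# ---------------------------------------------------------------------------
# Histograms


@dataclass
class OverlapHistogram:
    """Pooled MCO/TMO probability distributions for one strand pair.

    Value 0 encodes "not bonded" and is always present as a key.  Frames are
    pooled across runs with equal weight per frame.
    """

    pair: tuple[str, str]
    p_mco: dict[int, float]
    p_tmo: dict[int, float]
    n_frames_total: int
    n_runs: int

    def to_frame(self) -> pd.DataFrame:
        values = sorted(set(self.p_mco) | set(self.p_tmo))
        return pd.DataFrame(
            {
                "value": values,
                "p_mco": [self.p_mco.get(v, 0.0) for v in values],
                "p_tmo": [self.p_tmo.get(v, 0.0) for v in values],
            }
        )

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write(
            f"# MCO/TMO probabilities for {self.pair[0]}-{self.pair[1]}; "
            f"pooled over {self.n_runs} run(s), {self.n_frames_total} "
            "frames; value 0 = not bonded\n")
        self.to_frame().to_csv(buf, sep="\t", index=False)
        return buf.getvalue()


def _prob_table(values: np.ndarray) -> dict[int, float]:
    uniq, counts = np.unique(values, return_counts=True)
    probs = {int(v): float(c) / len(values) for v, c in zip(uniq, counts)}
    probs.setdefault(0, 0.0)
    return probs


def histogram(traces: Sequence[PairTrace]) -> OverlapHistogram:
    """Pool one pair's traces (one per run) into probability histograms."""
    traces = list(traces)
    if not traces:
        raise InputError("histogram needs at least one trace")
    pair = traces[0].pair
    if any(t.pair != pair for t in traces):
        raise InputError("all traces must describe the same strand pair")
    if sum(len(t) for t in traces) == 0:
        raise InputError("histogram needs at least one frame")
    mco = np.concatenate([t.mco for t in traces])
    tmo = np.concatenate([t.tmo for t in traces])
    return OverlapHistogram(
        pair=pair,
        p_mco=_prob_table(mco),
        p_tmo=_prob_table(tmo),
        n_frames_total=int(len(mco)),
        n_runs=len(traces),
    )


def ensemble_timeseries(
    traces: Sequence[PairTrace], smooth_window: int | None = None
) -> pd.DataFrame:
    """Pointwise mean MCO/TMO over runs sharing one step grid.

    Returns a frame with columns ``step``, ``mean_mco``, ``mean_tmo``.
    Optional boxcar smoothing (``smooth_window`` frames) is off by default.
    """
    traces = list(traces)
    if not traces:
        raise InputError("ensemble_timeseries needs at least one trace")
    grid = traces[0].steps
    for t in traces[1:]:
        if len(t.steps) != len(grid) or np.any(t.steps != grid):
            raise InputError(
                "traces do not share a step grid; resample them to a common "
                "grid before averaging")
    mean_mco = np.mean([t.mco for t in traces], axis=0)
    mean_tmo = np.mean([t.tmo for t in traces], axis=0)
    if smooth_window is not None:
        if smooth_window < 1:
            raise InputError("smooth_window must be >= 1")
        kernel = np.ones(smooth_window) / smooth_window
        mean_mco = np.convolve(mean_mco, kernel, mode="same")
        mean_tmo = np.convolve(mean_tmo, kernel, mode="same")
    return pd.DataFrame(
        {"step": grid, "mean_mco": mean_mco, "mean_tmo": mean_tmo})


# ---------------------------------------------------------------------------
# Binding events


@dataclass(frozen=True)
class BindingEvent:
    """A maximal stretch of frames with MCO at or above a threshold.

    ``lifetime_steps`` spans from the first frame of the event to one
    recording interval past its last frame, so a single-frame event lasts
    one interval.  ``censored`` marks events still in progress when the
    trace ends (the lifetime is then a lower bound); ``left_censored`` marks
    events already in progress at the first frame.
    """

    pair: tuple[str, str]
    start_step: int
    end_step: int
    lifetime_steps: int
    threshold: int
    censored: bool = False
    left_censored: bool = False


def binding_events(
    trace: PairTrace,
    threshold: int = 4,
    record_interval: int | None = None,
) -> list[BindingEvent]:
    """Maximal runs of consecutive frames with ``MCO >= threshold``.

    The default threshold of 4 consecutive paired bases is the minimum for
    an effective attachment between two strands; shorter contacts break too
    easily to count as binding.
    """
    if threshold < 1:
        raise InputError("threshold must be >= 1")
    if len(trace) == 0:
        return []
    interval = (record_interval if record_interval is not None
                else trace.record_interval())
    above = trace.mco >= threshold
    events: list[BindingEvent] = []
    start: int | None = None
    for idx in range(len(trace) + 1):
        on = idx < len(trace) and above[idx]
        if on and start is None:
            start = idx
        elif not on and start is not None:
            last = idx - 1
            start_step = int(trace.steps[start])
            end_step = int(trace.steps[last]) + interval
            events.append(
                BindingEvent(
                    pair=trace.pair,
                    start_step=start_step,
                    end_step=end_step,
                    lifetime_steps=end_step - start_step,
                    threshold=threshold,
                    censored=last == len(trace) - 1,
                    left_censored=start == 0,
                )
            )
            start = None
    return events


def events_to_frame(events: Sequence[BindingEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strand_a": e.pair[0],
                "strand_b": e.pair[1],
                "start_step": e.start_step,
                "end_step": e.end_step,
                "lifetime_steps": e.lifetime_steps,
                "threshold": e.threshold,
                "censored": e.censored,
                "left_censored": e.left_censored,
            }
            for e in events
        ],
        columns=["strand_a", "strand_b", "start_step", "end_step",
                 "lifetime_steps", "threshold", "censored", "left_censored"],
    )


# ---------------------------------------------------------------------------
# Complex detection


def default_species_of(strand_name: str) -> str:
    """Species label of a strand: the name minus any copy-number suffix.

    ``res_2`` and ``res2`` map to ``res``; short names whose digits are part
    of the species itself (``p4``, ``p10``) are kept whole.  Pass a custom
    ``species_of`` for other naming schemes.
    """
    stem, _, suffix = strand_name.rpartition("_")
    if stem and suffix.isdigit():
        return stem
    stripped = strand_name.rstrip("0123456789")
    if len(stripped) >= 2:
        return stripped
    return strand_name


_SIZE_LABEL = {1: "monomer", 2: "dimer", 3: "trimer", 4: "tetramer",
               5: "pentamer"}


def composition_label(members: Sequence[str],
                      species_of: Callable[[str], str] = default_species_of
                      ) -> str:
    """Label like ``'trimer[p10+p4+res]'`` or ``'tetramer[p10+p4+2xres]'``."""
    counts: dict[str, int] = {}
    for m in members:
        sp = species_of(m)
        counts[sp] = counts.get(sp, 0) + 1
    size = len(members)
    size_label = _SIZE_LABEL.get(size, f"{size}-mer")
    parts = [
        (f"{n}x{sp}" if n > 1 else sp) for sp, n in sorted(counts.items())
    ]
    return f"{size_label}[{'+'.join(parts)}]"


@dataclass
class ComplexEntry:
    """Connected components of the strand-contact graph in one frame."""

    step: int
    components: list[tuple[str, ...]]          # sorted member names
    labels: list[str]                          # parallel to components
    edge_overlap: dict[tuple[str, str], tuple[int, int]]  # pair -> (mco, tmo)


@dataclass
class ComplexReport:
    """Per-frame complexes plus per-composition occupancy over the run.

    ``occupancy`` is the fraction of all component instances (tallied per
    frame) carrying each composition label; the fractions sum to 1.
    """

    entries: list[ComplexEntry]
    occupancy: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            for comp, label in zip(e.components, e.labels):
                rows.append({"step": e.step, "label": label,
                             "members": "+".join(comp)})
        return pd.DataFrame(rows, columns=["step", "label", "members"])


def detect_complexes(
    frame: HBFrame,
    topo: Topology,
    min_edge: tuple[str, int] = ("tmo", 1),
    species_of: Callable[[str], str] = default_species_of,
) -> ComplexEntry:
    """Connected components of the strand graph in one frame.

    Two strands share an edge when the chosen statistic meets the rule
    ``min_edge = (stat, k)`` with ``stat`` in {"tmo", "mco"}; the default
    ``("tmo", 1)`` links strands joined by any bond (a parasite may attach
    via few, non-consecutive bonds).  Components are ordered by their sorted
    member tuple, so the output is deterministic.
    """
    stat, k = min_edge
    if stat not in ("tmo", "mco"):
        raise InputError("min_edge statistic must be 'tmo' or 'mco'")
    if k < 1:
        raise InputError("min_edge threshold must be >= 1")
    names = [topo.names[sid] for sid in sorted(topo.names)]
    graph = nx.Graph()
    graph.add_nodes_from(names)
    edge_overlap: dict[tuple[str, str], tuple[int, int]] = {}
    for idx, a in enumerate(names):
        for b in names[idx + 1:]:
            mco, tmo = frame_pair_overlap(frame, topo, a, b)
            if tmo:
                edge_overlap[(a, b)] = (mco, tmo)
            value = tmo if stat == "tmo" else mco
            if value >= k:
                graph.add_edge(a, b)
    components = sorted(
        tuple(sorted(c)) for c in nx.connected_components(graph))
    labels = [composition_label(c, species_of) for c in components]
    return ComplexEntry(frame.step, components, labels, edge_overlap)


def complex_report(
    frames: Iterable[HBFrame],
    topo: Topology,
    min_edge: tuple[str, int] = ("tmo", 1),
    species_of: Callable[[str], str] = default_species_of,
) -> ComplexReport:
    """Run :func:`detect_complexes` over a trajectory and tally compositions."""
    entries = [detect_complexes(f, topo, min_edge, species_of)
               for f in frames]
    tally: dict[str, int] = {}
    total = 0
    for e in entries:
        for label in e.labels:
            tally[label] = tally.get(label, 0) + 1
            total += 1
    occupancy = {lab: n / total for lab, n in sorted(tally.items())} \
        if total else {}
    return ComplexReport(entries, occupancy)


# ---------------------------------------------------------------------------
# Self-folding


@dataclass
class SelfFoldRecord:
    """Intra-strand pairing summary for one strand in one frame.

    ``loop_length`` is the number of unpaired bases closed off by the
    innermost pair of the longest intra-strand antiparallel run (the hairpin
    loop), or 0 when no run exists.
    """

    strand: str
    step: int
    n_intra_pairs: int
    longest_run: int
    loop_length: int


def self_fold(
    frame: HBFrame, topo: Topology, strand: str, min_loop: int = 3
) -> SelfFoldRecord:
    """Detect self-folding of one strand in one frame.

    Counts intra-strand bonds whose positions are more than ``min_loop``
    bases apart (a hairpin needs at least ``min_loop`` unpaired bases to
    turn); closer bonds are geometrically impossible and excluded.
    """
    sid = topo.strand_id_of_name(strand)
    intra: set[tuple[int, int]] = set()
    for i, j in frame.pairs:
        if topo.strand_of[i] == sid and topo.strand_of[j] == sid:
            li, lj = topo.local_index[i], topo.local_index[j]
            if abs(li - lj) > min_loop:
                intra.add((min(li, lj), max(li, lj)))
    longest = 0
    loop = 0
    for i, j in intra:
        if (i - 1, j + 1) in intra:
            continue
        k = 1
        while (i + k, j - k) in intra:
            k += 1
        if k > longest:
            longest = k
            inner_i, inner_j = i + k - 1, j - k + 1
            loop = inner_j - inner_i - 1
    return SelfFoldRecord(
        strand=strand,
        step=frame.step,
        n_intra_pairs=len(intra),
        longest_run=longest,
        loop_length=loop,
    )


# ---------------------------------------------------------------------------
# Run summary


def run_summary(
    traces: Mapping[tuple[str, str], PairTrace] | Sequence[PairTrace],
    threshold: int = 4,
) -> dict:
    """JSON-ready summary: per-pair bound fraction, histogram modes, events."""
    if isinstance(traces, Mapping):
        traces = list(traces.values())
    out: dict = {"pairs": {}}
    for t in traces:
        hist = histogram([t])
        events = binding_events(t, threshold=threshold)
        lifetimes = [e.lifetime_steps for e in events]
        out["pairs"]["-".join(t.pair)] = {
            "n_frames": len(t),
            "bound_fraction": t.bound_fraction,
            "p_mco": {str(k): v for k, v in sorted(hist.p_mco.items())},
            "p_tmo": {str(k): v for k, v in sorted(hist.p_tmo.items())},
            "n_events": len(events),
            "mean_lifetime_steps":
                float(np.mean(lifetimes)) if lifetimes else 0.0,
            "threshold": threshold,
        }
    return out


def summary_to_json(summary: dict, **kwargs) -> str:
    return json.dumps(summary, **kwargs)
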
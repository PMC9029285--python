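"""Synthetic hydrogen-bond trajectories with known ground truth.

The MD engine that produced the real bond lists is expensive and stochastic;
this module emulates the *statistical* structure of its output so that every
stage of the analysis pipeline can be exercised and validated offline.

Each strand pair follows an alternating-renewal chain: unbound sojourns and
bound sojourns with geometrically distributed dwell times (in frames).  At
the start of a bound sojourn the pair draws a run length ``m`` from its
configured stationary distribution, one of the pair's omega windows, and a
placement of the ``m``-run inside that window; every frame of the sojourn
then shows that antiparallel run, optionally decorated with isolated extra
complementary pairs at the same register (so TMO exceeds MCO) that are kept
non-adjacent to the run and to each other.  Because the dwell laws are
memoryless and shared by all bound states, the per-frame distribution of
MCO equals the configured stationary probabilities, and the mean binding
event length equals the configured bound dwell — both of which the analysis
must recover.

Pairs evolve independently; when two pairs claim the same nucleotide in the
same frame the earlier pair in the configuration order wins and the loser
contributes no bonds that frame (the conflict is logged).  In a
predator/predator/resource scenario whose omega windows overlap on the
resource this produces competitive exclusion: the lower-priority predator is
pushed off the resource whenever the other predator occupies the shared
bases.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InputError
from .overlap import (
    P4_SEQ,
    P10_SEQ,
    RES_SEQ,
    Oligomer,
    OmegaWindow,
    complementary,
    profile,
)
from .oxdna import (
    Configuration,
    HBFrame,
    Topology,
    topology_from_oligomers,
    write_configuration,
    write_hb_frames,
    write_topology,
)

# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PairKinetics:
    """Stationary/kinetic parameters of one strand pair's binding chain.

    ``run_probs[m]`` is the stationary probability that a frame shows an
    antiparallel run of exactly ``m`` consecutive bonds; together with
    ``p_unbound`` the probabilities must sum to 1 and every ``m`` must not
    exceed the pair's omega.  Dwell times are geometric with the given means
    (frames); ``mean_dwell_unbound`` defaults to the value that realizes
    ``p_unbound`` under alternating renewal,
    ``d_u = d_b * p_unbound / (1 - p_unbound)``.
    ``extra_pair_rate`` is the per-candidate per-frame probability of an
    isolated extra pair outside the run (raises TMO above MCO).
    """

    pair: tuple[str, str]
    p_unbound: float
    run_probs: dict[int, float]
    mean_dwell_bound: float = 10.0
    mean_dwell_unbound: float | None = None
    extra_pair_rate: float = 0.0
    window_weights: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_unbound <= 1.0:
            raise InputError("p_unbound must lie in [0, 1]")
        total = self.p_unbound + sum(self.run_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(
                f"stationary probabilities sum to {total}, expected 1")
        if any(m < 1 for m in self.run_probs):
            raise InputError("run lengths must be >= 1")
        if any(p < 0 for p in self.run_probs.values()):
            raise InputError("run probabilities must be non-negative")
        if self.mean_dwell_bound < 1:
            raise InputError("mean_dwell_bound must be >= 1 frame")
        if not 0.0 <= self.extra_pair_rate <= 1.0:
            raise InputError("extra_pair_rate must lie in [0, 1]")

    def dwell_unbound(self) -> float:
        if self.mean_dwell_unbound is not None:
            return self.mean_dwell_unbound
        if self.p_unbound >= 1.0:
            return np.inf
        if self.p_unbound == 0.0:
            return 1.0  # never used: the chain never leaves the bound side
        return self.mean_dwell_bound * self.p_unbound / (1 - self.p_unbound)


@dataclass
class ScenarioConfig:
    """A full synthetic scenario: strands, per-pair kinetics, frame grid."""

    oligomers: list[Oligomer]
    kinetics: list[PairKinetics]
    n_frames: int
    record_interval: int = 1_000
    rng_seed: int = 0
    box: float = 40.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise InputError("n_frames must be >= 1")
        names = {o.name for o in self.oligomers}
        if len(names) != len(self.oligomers):
            raise InputError("oligomer names must be unique")
        for kin in self.kinetics:
            for s in kin.pair:
                if s not in names:
                    raise InputError(
                        f"kinetics references unknown strand {s!r}")

    def to_dict(self) -> dict:
        return {
            "oligomers": [{"name": o.name, "seq": o.seq}
                          for o in self.oligomers],
            "kinetics": [
                {
                    "pair": list(k.pair),
                    "p_unbound": k.p_unbound,
                    "run_probs": {str(m): p
                                  for m, p in sorted(k.run_probs.items())},
                    "mean_dwell_bound": k.mean_dwell_bound,
                    "mean_dwell_unbound": k.mean_dwell_unbound,
                    "extra_pair_rate": k.extra_pair_rate,
                    "window_weights": (list(k.window_weights)
                                       if k.window_weights else None),
                }
                for k in self.kinetics
            ],
            "n_frames": self.n_frames,
            "record_interval": self.record_interval,
            "rng_seed": self.rng_seed,
            "box": self.box,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(
            oligomers=[Oligomer(o["name"], o["seq"])
                       for o in d["oligomers"]],
            kinetics=[
                PairKinetics(
                    pair=tuple(k["pair"]),
                    p_unbound=k["p_unbound"],
                    run_probs={int(m): p
                               for m, p in k["run_probs"].items()},
                    mean_dwell_bound=k.get("mean_dwell_bound", 10.0),
                    mean_dwell_unbound=k.get("mean_dwell_unbound"),
                    extra_pair_rate=k.get("extra_pair_rate", 0.0),
                    window_weights=k.get("window_weights"),
                )
                for k in d["kinetics"]
            ],
            n_frames=d["n_frames"],
            record_interval=d.get("record_interval", 1_000),
            rng_seed=d.get("rng_seed", 0),
            box=d.get("box", 40.0),
        )


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests.

    ``sojourns`` records every state visit per pair (state, dwell, window,
    run placement); ``conflicts`` records frames where a pair's bonds were
    dropped because a higher-priority pair already occupied a nucleotide,
    and ``exclusions`` the subset of conflicts contested on a shared
    resource strand.
    """

    config: ScenarioConfig
    sojourns: dict[tuple[str, str], list[dict]] = field(default_factory=dict)
    conflicts: list[dict] = field(default_factory=list)
    exclusions: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "sojourns": {"-".join(pair): entries
                         for pair, entries in self.sojourns.items()},
            "conflicts": self.conflicts,
            "exclusions": self.exclusions,
        }


# ---------------------------------------------------------------------------
# Chain generation


@dataclass
class _PairPlan:
    """Precomputed geometry for one pair: windows and extra-pair slots."""

    kin: PairKinetics
    omega: int
    windows: list[OmegaWindow]
    # per window: candidate extra pairs [(local1, local2)] sorted by local1
    extra_candidates: list[list[tuple[int, int]]]
    offsets: tuple[int, int]  # global offset of each strand


def _pair_plan(config: ScenarioConfig, topo: Topology,
               kin: PairKinetics) -> _PairPlan:
    by_name = {o.name: o for o in config.oligomers}
    o1, o2 = by_name[kin.pair[0]], by_name[kin.pair[1]]
    prof = profile(o1, o2)
    if prof.omega < 1 and kin.run_probs:
        raise InputError(
            f"pair {kin.pair}: no complementary window exists (omega = 0) "
            "but bound states are configured")
    if any(m > prof.omega for m in kin.run_probs):
        raise InputError(
            f"pair {kin.pair}: configured run length exceeds omega = "
            f"{prof.omega}")
    if kin.window_weights is not None and \
            len(kin.window_weights) != len(prof.windows):
        raise InputError(
            f"pair {kin.pair}: {len(prof.windows)} omega windows but "
            f"{len(kin.window_weights)} window weights")
    L, l = len(o1), len(o2)
    candidates: list[list[tuple[int, int]]] = []
    for w in prof.windows:
        cand = []
        for i in range(max(0, w.r), min(L, w.r + l)):
            j = l - 1 - (i - w.r)
            if complementary(o1.seq[i], o2.seq[j]):
                cand.append((i, j))
        candidates.append(sorted(cand))
    offsets = {}
    g = 0
    for o in config.oligomers:
        offsets[o.name] = g
        g += len(o)
    return _PairPlan(kin, prof.omega, prof.windows, candidates,
                     (offsets[o1.name], offsets[o2.name]))


def _draw_dwell(rng: np.random.Generator, mean: float) -> int:
    if not np.isfinite(mean):
        return np.iinfo(np.int64).max
    return int(rng.geometric(1.0 / mean))


def _pair_states(
    rng: np.random.Generator, plan: _PairPlan, n_frames: int
) -> tuple[list[tuple[int, int, int]], list[dict]]:
    """Per-frame state of one pair plus the sojourn log.

    A state is ``(m, window_index, offset)`` with ``m = 0`` meaning unbound.
    """
    kin = plan.kin
    run_lengths = sorted(kin.run_probs)
    p_bound = 1.0 - kin.p_unbound
    cond = (np.array([kin.run_probs[m] for m in run_lengths]) / p_bound
            if p_bound > 0 else None)
    if kin.window_weights is not None:
        w_weights = np.asarray(kin.window_weights, dtype=float)
        w_weights = w_weights / w_weights.sum()
    else:
        w_weights = None
    states: list[tuple[int, int, int]] = []
    sojourns: list[dict] = []
    bound = bool(rng.random() >= kin.p_unbound) if p_bound > 0 else False
    frame = 0
    while frame < n_frames:
        if bound:
            m = int(rng.choice(run_lengths, p=cond))
            widx = int(rng.choice(len(plan.windows), p=w_weights))
            off = int(rng.integers(0, plan.omega - m + 1))
            dwell = _draw_dwell(rng, kin.mean_dwell_bound)
            state = (m, widx, off)
        else:
            dwell = _draw_dwell(rng, kin.dwell_unbound())
            state = (0, -1, -1)
        dwell = min(dwell, n_frames - frame)
        states.extend([state] * dwell)
        sojourns.append(
            {
                "state": "bound" if bound else "unbound",
                "m": state[0],
                "window": state[1],
                "offset": state[2],
                "start_frame": frame,
                "n_frames": dwell,
            }
        )
        frame += dwell
        bound = not bound if 0.0 < kin.p_unbound < 1.0 else bound
    return states, sojourns


def _state_bonds(
    rng: np.random.Generator, plan: _PairPlan, state: tuple[int, int, int]
) -> list[tuple[int, int]]:
    """Global-index bonds realizing a pair state in one frame."""
    m, widx, off = state
    if m == 0:
        return []
    w = plan.windows[widx]
    g1, g2 = plan.offsets
    run_start = w.start1 + off
    bonds = [
        (g1 + run_start + k, g2 + w.start2 + (w.length - 1) - (off + k))
        for k in range(m)
    ]
    if plan.kin.extra_pair_rate > 0.0:
        taken = set(range(run_start - 1, run_start + m + 1))
        for i, j in plan.extra_candidates[widx]:
            if i in taken:
                continue
            if rng.random() < plan.kin.extra_pair_rate:
                bonds.append((g1 + i, g2 + j))
                taken.update((i - 1, i, i + 1))
    return bonds


def generate_trajectory(
    config: ScenarioConfig,
) -> tuple[Topology, list[HBFrame], GroundTruth]:
    """Draw a full synthetic trajectory from the per-pair chains.

    Frames are stamped ``0, record_interval, 2*record_interval, ...``.
    Deterministic for a given ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    topo = topology_from_oligomers(config.oligomers)
    truth = GroundTruth(config=config)
    plans = [_pair_plan(config, topo, kin) for kin in config.kinetics]
    per_pair_states = []
    for plan in plans:
        states, sojourns = _pair_states(rng, plan, config.n_frames)
        per_pair_states.append(states)
        truth.sojourns[plan.kin.pair] = sojourns
    resource = _shared_strand(config)
    frames: list[HBFrame] = []
    for f in range(config.n_frames):
        frame = HBFrame(step=f * config.record_interval)
        occupied: set[int] = set()
        for plan, states in zip(plans, per_pair_states):
            bonds = _state_bonds(rng, plan, states[f])
            if not bonds:
                continue
            flat = {k for b in bonds for k in b}
            clash = flat & occupied
            if clash:
                record = {
                    "frame": f,
                    "step": frame.step,
                    "pair": list(plan.kin.pair),
                    "n_bonds_dropped": len(bonds),
                    "contested": sorted(clash),
                }
                truth.conflicts.append(record)
                if resource is not None and any(
                        topo.names[topo.strand_of[k]] == resource
                        for k in clash):
                    truth.exclusions.append(record)
                continue
            for i, j in bonds:
                frame.pairs.add((min(i, j), max(i, j)))
            occupied |= flat
        frames.append(frame)
    return topo, frames, truth


def _window_cover(config: ScenarioConfig, strand: str, partner: str
                  ) -> set[int]:
    """Local positions on ``strand`` covered by its omega windows with
    ``partner``."""
    by_name = {o.name: o for o in config.oligomers}
    prof = profile(by_name[partner], by_name[strand])
    cover: set[int] = set()
    for w in prof.windows:
        cover |= set(range(w.start2, w.start2 + w.length))
    return cover


def _shared_strand(config: ScenarioConfig) -> str | None:
    """The contested resource: a strand bound by >= 2 partners whose omega
    windows overlap on it.  Falls back to any multiply-bound strand; None
    when every strand appears in at most one pair."""
    partners: dict[str, list[str]] = {}
    for kin in config.kinetics:
        a, b = kin.pair
        partners.setdefault(a, []).append(b)
        partners.setdefault(b, []).append(a)
    shared = [s for s, ps in partners.items() if len(ps) >= 2]
    if not shared:
        return None
    for s in shared:
        covers = [_window_cover(config, s, p) for p in partners[s]]
        for i, ci in enumerate(covers):
            for cj in covers[i + 1:]:
                if ci & cj:
                    return s
    return shared[0]


def generate_competition(
    config: ScenarioConfig,
) -> tuple[Topology, list[HBFrame], GroundTruth]:
    """Generate a scenario where predators contend for one resource strand.

    Requires (and checks) that at least two kinetics pairs share a strand
    and that their omega windows overlap on it — otherwise there is no
    exclusion to emulate and a warning is logged.  The one-bond-per-base
    rule then forbids simultaneous occupancy of the shared bases; dropped
    attempts are logged as exclusion events in the ground truth.
    """
    import logging

    resource = _shared_strand(config)
    if resource is None:
        raise InputError(
            "competition needs at least two pairs sharing a strand")
    by_name = {o.name: o for o in config.oligomers}
    spans = []
    for kin in config.kinetics:
        if resource not in kin.pair:
            continue
        other = kin.pair[0] if kin.pair[1] == resource else kin.pair[1]
        prof = profile(by_name[other], by_name[resource])
        cover: set[int] = set()
        for w in prof.windows:
            cover |= set(range(w.start2, w.start2 + w.length))
        spans.append(cover)
    overlap = set.intersection(*spans) if spans else set()
    if not overlap:
        logging.getLogger(__name__).warning(
            "predator omega windows do not overlap on %r: no exclusion to "
            "emulate", resource)
    return generate_trajectory(config)


# ---------------------------------------------------------------------------
# Presets


def _reference_oligomers() -> dict[str, Oligomer]:
    return {
        "p4": Oligomer("p4", P4_SEQ),
        "p10": Oligomer("p10", P10_SEQ),
        "res": Oligomer("res", RES_SEQ),
    }


def _p4res_kinetics() -> PairKinetics:
    # ~25% unbound, run = omega for 60% of frames, remainder on short runs;
    # frequent extra pairs push TMO a few bonds above MCO.
    return PairKinetics(
        pair=("p4", "res"),
        p_unbound=0.25,
        run_probs={4: 0.60, 3: 0.05, 2: 0.05, 1: 0.05},
        mean_dwell_bound=10.0,
        extra_pair_rate=0.25,
    )


def _p10res_kinetics() -> PairKinetics:
    # strong binder: run = omega > 50% of frames, omega-1 for 30%,
    # TMO rarely more than 1-2 above MCO.
    return PairKinetics(
        pair=("p10", "res"),
        p_unbound=0.15,
        run_probs={10: 0.55, 9: 0.30},
        mean_dwell_bound=10.0,
        extra_pair_rate=0.10,
    )


PRESET_NAMES = ("p4res", "p10res", "p4p10", "competition3")


def preset(name: str, n_frames: int = 10_000, rng_seed: int = 0,
           record_interval: int = 1_000) -> ScenarioConfig:
    """Shipped scenario presets built on the reference p4/p10/res strands."""
    ref = _reference_oligomers()
    if name == "p4res":
        return ScenarioConfig(
            oligomers=[ref["p4"], ref["res"]],
            kinetics=[_p4res_kinetics()],
            n_frames=n_frames, record_interval=record_interval,
            rng_seed=rng_seed)
    if name == "p10res":
        return ScenarioConfig(
            oligomers=[ref["p10"], ref["res"]],
            kinetics=[_p10res_kinetics()],
            n_frames=n_frames, record_interval=record_interval,
            rng_seed=rng_seed)
    if name == "p4p10":
        return ScenarioConfig(
            oligomers=[ref["p4"], ref["p10"]],
            kinetics=[
                PairKinetics(
                    pair=("p4", "p10"),
                    p_unbound=0.20,
                    run_probs={7: 0.50, 5: 0.10, 4: 0.10, 3: 0.05, 2: 0.05},
                    mean_dwell_bound=10.0,
                    extra_pair_rate=0.30,
                )
            ],
            n_frames=n_frames, record_interval=record_interval,
            rng_seed=rng_seed)
    if name == "competition3":
        # priority order: the strong binder claims the resource first.
        return ScenarioConfig(
            oligomers=[ref["p10"], ref["p4"], ref["res"]],
            kinetics=[
                PairKinetics(
                    pair=("p10", "res"),
                    p_unbound=0.25,
                    run_probs={10: 0.55, 9: 0.20},
                    mean_dwell_bound=10.0,
                    extra_pair_rate=0.10,
                ),
                _p4res_kinetics(),
                PairKinetics(
                    pair=("p4", "p10"),
                    p_unbound=0.70,
                    run_probs={7: 0.20, 5: 0.10},
                    mean_dwell_bound=10.0,
                    extra_pair_rate=0.10,
                ),
            ],
            n_frames=n_frames, record_interval=record_interval,
            rng_seed=rng_seed)
    raise InputError(
        f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")


# ---------------------------------------------------------------------------
# Fixture files


def make_fixture_files(config: ScenarioConfig, out_dir: str | Path,
                       competition: bool | None = None) -> dict[str, Path]:
    """Write a scenario to disk in the simulation text dialects.

    Emits a topology, a bond-list trajectory, an initial configuration with
    placeholder coordinates, and a ground-truth JSON (which also carries the
    strand names so that reading the files back reproduces the in-memory
    objects).  Output is byte-stable for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if competition is None:
        competition = _shared_strand(config) is not None
    gen = generate_competition if competition else generate_trajectory
    topo, frames, truth = gen(config)
    paths = {
        "topology": out_dir / "topology.top",
        "bonds": out_dir / "bonds.hb",
        "configuration": out_dir / "init.conf",
        "ground_truth": out_dir / "ground_truth.json",
    }
    write_topology(topo, str(paths["topology"]))
    write_hb_frames(frames, str(paths["bonds"]))
    positions = _placeholder_positions(config)
    write_configuration(
        Configuration(step=0, box=(config.box,) * 3,
                      energies=(0.0, 0.0, 0.0), positions=positions),
        str(paths["configuration"]))
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def _placeholder_positions(config: ScenarioConfig) -> np.ndarray:
    """Deterministic straight-line placeholder coordinates, one strand per
    row of the box; not a physical configuration."""
    rows = []
    for s, o in enumerate(config.oligomers):
        for k in range(len(o)):
            rows.append((0.65 * k, 2.0 * (s + 1), config.box / 2.0))
    return np.array(rows)
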
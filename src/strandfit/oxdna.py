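"""Readers/writers for the coarse-grained DNA simulation text dialects.

Three plain-text formats are consumed by the trajectory analysis:

* **topology** — header ``"N n_strands"`` then one line per nucleotide:
  ``strand_id base neighbor_3 neighbor_5`` (global 0-based indices, -1 at a
  strand end).  Strand sequences are recovered 5'->3' by walking each
  strand's neighbor chain, so either listing order is accepted.
* **bond list** — per recorded frame, a step-stamp header (``t = <int>``,
  optionally prefixed ``#``) followed by ``i j`` lines giving the global
  indices of hydrogen-bonded nucleotides; extra columns (e.g. energies) and
  ``#`` comments are tolerated.
* **configuration** — ``t = ...``, ``b = Lx Ly Lz``, ``E = ...`` headers then
  15 floats per nucleotide (position, two orientation versors, velocity,
  angular velocity); only headers and positions are retained.

Also houses the MD-unit conversions (a timestep of 0.005 simulation units is
~15 fs; frames are recorded every 10^3 steps by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np

from .errors import InputError, ParseError
from .overlap import Oligomer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimUnits:
    """MD unit constants for converting step counts to physical time."""

    dt_steps: float = 0.005          # one MD timestep, simulation units
    fs_per_step: float = 15.0        # ~15 fs per MD timestep
    record_interval: int = 1_000     # steps between recorded frames
    nm_per_length_unit: float = 34.072 / 40.0

    def __post_init__(self) -> None:
        for f in ("dt_steps", "fs_per_step", "record_interval",
                  "nm_per_length_unit"):
            if getattr(self, f) <= 0:
                raise InputError(f"SimUnits.{f} must be positive")


_TIME_SCALE_FS = {"fs": 1.0, "ps": 1e3, "ns": 1e6, "us": 1e9, "µs": 1e9}


def steps_to_time(
    steps: int, units: SimUnits = SimUnits(), unit: str = "us"
) -> float:
    """Physical time spanned by ``steps`` MD steps, in ``unit`` (fs/ps/ns/us).

    10^8 steps at 15 fs/step is ~1.5 microseconds.
    """
    if steps < 0:
        raise InputError("step count must be non-negative")
    if unit not in _TIME_SCALE_FS:
        raise InputError(f"unknown time unit {unit!r}; use fs/ps/ns/us")
    return steps * units.fs_per_step / _TIME_SCALE_FS[unit]


# ---------------------------------------------------------------------------
# Topology


@dataclass
class Topology:
    """Strand composition of a simulated system.

    Global nucleotide indices are 0-based; strand ids are 1-based as in the
    topology dialect.  ``names`` maps strand id to a human-readable label
    (defaults to ``strand<id>``) used throughout the analysis output.
    """

    n_nucleotides: int
    n_strands: int
    strand_ids: list[int]            # per nucleotide, 1-based
    bases: list[str]                 # per nucleotide
    neighbors_3: list[int]           # per nucleotide, -1 at the 3' terminus
    neighbors_5: list[int]
    names: dict[int, str] = field(default_factory=dict)

    # derived, filled by _index()
    strand_of: list[int] = field(default_factory=list, repr=False)
    local_index: list[int] = field(default_factory=list, repr=False)
    strand_seqs: dict[int, Oligomer] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for sid in range(1, self.n_strands + 1):
            self.names.setdefault(sid, f"strand{sid}")
        self._index()

    def _walk_strand(self, members: list[int]) -> list[int]:
        """Order a strand's nucleotides 5'->3' by following neighbor links."""
        member_set = set(members)
        five_prime = [i for i in members if self.neighbors_5[i] == -1]
        if len(five_prime) != 1:
            raise ParseError(
                f"strand {self.strand_ids[members[0]]}: expected exactly one "
                f"5' terminus, found {len(five_prime)} (broken or cyclic "
                "neighbor chain)"
            )
        order = []
        i = five_prime[0]
        while i != -1:
            if i not in member_set or len(order) > len(members):
                raise ParseError(
                    f"strand {self.strand_ids[members[0]]}: neighbor chain "
                    "leaves the strand or cycles"
                )
            order.append(i)
            i = self.neighbors_3[i]
        if len(order) != len(members):
            raise ParseError(
                f"strand {self.strand_ids[members[0]]}: neighbor chain covers "
                f"{len(order)} of {len(members)} nucleotides"
            )
        return order

    def _index(self) -> None:
        n = self.n_nucleotides
        if not (len(self.strand_ids) == len(self.bases)
                == len(self.neighbors_3) == len(self.neighbors_5) == n):
            raise ParseError("per-nucleotide record count mismatch")
        members: dict[int, list[int]] = {}
        for i, sid in enumerate(self.strand_ids):
            members.setdefault(sid, []).append(i)
        if len(members) != self.n_strands:
            raise ParseError(
                f"header declares {self.n_strands} strands but records use "
                f"{len(members)} strand ids"
            )
        self.strand_of = [0] * n
        self.local_index = [0] * n
        self.strand_seqs = {}
        for sid, idxs in members.items():
            order = self._walk_strand(idxs)
            seq = "".join(self.bases[i] for i in order)
            self.strand_seqs[sid] = Oligomer(self.names[sid], seq)
            for pos, i in enumerate(order):
                self.strand_of[i] = sid
                self.local_index[i] = pos

    # -- lookups ----------------------------------------------------------
    def strand_id_of_name(self, name: str) -> int:
        for sid, nm in self.names.items():
            if nm == name:
                return sid
        raise InputError(f"unknown strand name {name!r}; "
                         f"known: {sorted(self.names.values())}")

    def resolve(self, global_index: int) -> tuple[str, int]:
        """(strand name, 0-based 5'->3' local index) of a nucleotide."""
        if not 0 <= global_index < self.n_nucleotides:
            raise InputError(f"nucleotide index {global_index} out of range")
        return (self.names[self.strand_of[global_index]],
                self.local_index[global_index])

    def global_index(self, strand_name: str, local: int) -> int:
        sid = self.strand_id_of_name(strand_name)
        seq = self.strand_seqs[sid]
        if not 0 <= local < len(seq):
            raise InputError(
                f"local index {local} out of range for {strand_name!r}")
        for i in range(self.n_nucleotides):
            if self.strand_of[i] == sid and self.local_index[i] == local:
                return i
        raise AssertionError("index maps out of sync")  # pragma: no cover


def read_topology(stream: IO[str] | str, names: Iterable[str] | None = None
                  ) -> Topology:
    """Parse a topology file; ``names`` optionally labels strands in id order."""
    if isinstance(stream, str):
        with open(stream) as fh:
            return read_topology(fh, names)
    lines = stream.read().splitlines()
    if not lines:
        raise ParseError("empty topology file", line=1)
    header = lines[0].split()
    if len(header) != 2:
        raise ParseError("header must be 'N n_strands'", line=1)
    try:
        n, n_strands = int(header[0]), int(header[1])
    except ValueError:
        raise ParseError("header must hold two integers", line=1) from None
    records = [ln for ln in lines[1:] if ln.strip()]
    if len(records) != n:
        raise ParseError(
            f"header declares {n} nucleotides but file has {len(records)} "
            "records")
    strand_ids, bases, n3, n5 = [], [], [], []
    for k, ln in enumerate(records, start=2):
        tok = ln.split()
        if len(tok) != 4:
            raise ParseError("expected 'strand base neighbor3 neighbor5'",
                             line=k)
        try:
            strand_ids.append(int(tok[0]))
            n3.append(int(tok[2]))
            n5.append(int(tok[3]))
        except ValueError:
            raise ParseError("non-integer strand id or neighbor", line=k
                             ) from None
        if tok[1].upper() not in "ACGT" or len(tok[1]) != 1:
            raise ParseError(f"unknown base letter {tok[1]!r}", line=k)
        bases.append(tok[1].upper())
    name_map = {}
    if names is not None:
        name_map = {sid: nm for sid, nm in
                    zip(range(1, n_strands + 1), names)}
    return Topology(n, n_strands, strand_ids, bases, n3, n5, names=name_map)


def write_topology(topo: Topology, stream: IO[str] | str) -> None:
    """Write the canonical form: records in global index order."""
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            write_topology(topo, fh)
            return
    stream.write(f"{topo.n_nucleotides} {topo.n_strands}\n")
    for i in range(topo.n_nucleotides):
        stream.write(
            f"{topo.strand_ids[i]} {topo.bases[i]} "
            f"{topo.neighbors_3[i]} {topo.neighbors_5[i]}\n")


def topology_from_oligomers(oligomers: Iterable[Oligomer]) -> Topology:
    """Build a topology for a set of strands, indices assigned 5'->3'."""
    oligomers = list(oligomers)
    strand_ids, bases, n3, n5, names = [], [], [], [], {}
    g = 0
    for sid, oligo in enumerate(oligomers, start=1):
        names[sid] = oligo.name
        L = len(oligo)
        for k, b in enumerate(oligo.seq):
            strand_ids.append(sid)
            bases.append(b)
            n5.append(g + k - 1 if k > 0 else -1)
            n3.append(g + k + 1 if k < L - 1 else -1)
        g += L
    return Topology(g, len(oligomers), strand_ids, bases, n3, n5, names=names)


# ---------------------------------------------------------------------------
# Hydrogen-bond frames


@dataclass
class HBFrame:
    """One recorded frame's hydrogen-bonded nucleotide pairs.

    ``pairs`` holds unordered global-index pairs stored as sorted tuples.  A
    nucleotide can appear in at most one pair per frame; duplicates are
    dropped on read (first occurrence wins) with a logged warning.
    """

    step: int
    pairs: set[tuple[int, int]] = field(default_factory=set)

    def add(self, i: int, j: int) -> bool:
        """Add a bond unless either base is already paired; True if added."""
        if i == j:
            raise InputError("a nucleotide cannot pair with itself")
        occupied = {k for p in self.pairs for k in p}
        if i in occupied or j in occupied:
            return False
        self.pairs.add((min(i, j), max(i, j)))
        return True

    def validate(self, topo: Topology) -> None:
        occupied: set[int] = set()
        for i, j in self.pairs:
            for k in (i, j):
                if not 0 <= k < topo.n_nucleotides:
                    raise InputError(
                        f"frame at step {self.step}: index {k} exceeds "
                        f"topology size {topo.n_nucleotides}")
                if k in occupied:
                    raise InputError(
                        f"frame at step {self.step}: nucleotide {k} bonded "
                        "twice")
                occupied.add(k)


_STEP_TOKENS = ("t",)


def _parse_step_header(line: str) -> int | None:
    """Recognize 't = <int>' / '# t = <int>' step-stamp headers."""
    stripped = line.strip()
    if stripped.startswith("#"):
        stripped = stripped[1:].strip()
    parts = stripped.replace("=", " = ").split()
    if len(parts) == 3 and parts[0] in _STEP_TOKENS and parts[1] == "=":
        try:
            return int(parts[2])
        except ValueError:
            return None
    return None


def read_hb_frames(stream: IO[str] | str) -> Iterator[HBFrame]:
    """Lazily yield bond-list frames in file order.

    Step stamps must be non-decreasing; a decreasing stamp raises
    :class:`ParseError`.  Within a frame only the first pair touching a
    nucleotide is kept (one bond per base); later ones are dropped with a
    warning.  Extra per-line columns beyond the first two integers are
    ignored.
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            yield from read_hb_frames(fh)
            return
    frame: HBFrame | None = None
    last_step: int | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        step = _parse_step_header(line)
        if step is not None:
            if last_step is not None and step < last_step:
                raise ParseError(
                    f"step stamp {step} decreases (previous {last_step})",
                    line=lineno)
            if frame is not None:
                yield frame
            frame = HBFrame(step)
            last_step = step
            continue
        if line.startswith("#"):
            continue
        if frame is None:
            raise ParseError("bond line before any step-stamp header",
                             line=lineno)
        tok = line.split()
        try:
            i, j = int(tok[0]), int(tok[1])
        except (ValueError, IndexError):
            raise ParseError(
                f"expected two integer indices, got {line!r}", line=lineno
            ) from None
        if not frame.add(i, j):
            logger.warning(
                "line %d: pair (%d, %d) dropped, a base is already bonded "
                "in frame at step %d", lineno, i, j, frame.step)
    if frame is not None:
        yield frame


def write_hb_frames(frames: Iterable[HBFrame], stream: IO[str] | str) -> None:
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            write_hb_frames(frames, fh)
            return
    for frame in frames:
        stream.write(f"# t = {frame.step}\n")
        for i, j in sorted(frame.pairs):
            stream.write(f"{i} {j}\n")


# ---------------------------------------------------------------------------
# Configuration files


@dataclass
class Configuration:
    """Headers and positions of one configuration record."""

    step: int
    box: tuple[float, float, float]
    energies: tuple[float, ...]
    positions: np.ndarray  # (n, 3)


def _header_floats(line: str, key: str, lineno: int) -> list[float]:
    parts = line.split("=")
    if len(parts) != 2 or parts[0].strip().lower() != key:
        raise ParseError(f"expected '{key} = ...' header", line=lineno)
    try:
        return [float(x) for x in parts[1].split()]
    except ValueError:
        raise ParseError(f"non-numeric {key} header", line=lineno) from None


def read_configuration(stream: IO[str] | str) -> Configuration:
    """Parse one configuration record (headers + 15 floats per nucleotide).

    Orientations and velocities are parsed for validation but discarded;
    only positions are kept.
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            return read_configuration(fh)
    lines = [ln for ln in stream.read().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ParseError("configuration needs t/b/E headers", line=1)
    t_vals = _header_floats(lines[0], "t", 1)
    if len(t_vals) != 1:
        raise ParseError("t header must hold one value", line=1)
    box = _header_floats(lines[1], "b", 2)
    if len(box) != 3:
        raise ParseError("b header must hold three box lengths", line=2)
    energies = tuple(_header_floats(lines[2], "e", 3))
    positions = []
    for lineno, ln in enumerate(lines[3:], start=4):
        tok = ln.split()
        if len(tok) != 15:
            raise ParseError(
                f"expected 15 floats per nucleotide, got {len(tok)}",
                line=lineno)
        try:
            vals = [float(x) for x in tok]
        except ValueError:
            raise ParseError("non-numeric coordinate", line=lineno) from None
        positions.append(vals[:3])
    return Configuration(
        step=int(t_vals[0]),
        box=(box[0], box[1], box[2]),
        energies=energies,
        positions=np.array(positions).reshape(-1, 3),
    )


def read_configuration_header(stream: IO[str] | str
                              ) -> tuple[int, tuple[float, float, float],
                                         tuple[float, ...]]:
    """(step, box, energies) of a configuration record."""
    conf = read_configuration(stream)
    return conf.step, conf.box, conf.energies


def write_configuration(conf: Configuration, stream: IO[str] | str) -> None:
    """Write a configuration with placeholder orientations/velocities."""
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            write_configuration(conf, fh)
            return
    stream.write(f"t = {conf.step}\n")
    stream.write("b = " + " ".join(f"{x:g}" for x in conf.box) + "\n")
    stream.write("E = " + " ".join(f"{x:g}" for x in conf.energies) + "\n")
    for pos in conf.positions:
        fields = [f"{x:.6f}" for x in pos]
        fields += ["1", "0", "0", "0", "1", "0"]      # orientation versors
        fields += ["0"] * 6                           # velocities
        stream.write(" ".join(fields) + "\n")
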
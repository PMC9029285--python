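"""Combinatorial hybridization scoring between ssDNA oligomers.

Two single strands held at a fixed relative position can pair wherever
opposing bases are Watson-Crick complementary (A/T, C/G).  For each relative
position ``r`` we score

* ``MCO|r`` — the maximum consecutive overlap: the longest run of adjacent
  complementary opposing bases, and
* ``TMO|r`` — the total mixed overlap: the total count of complementary
  opposing bases (so ``TMO|r >= MCO|r`` always).

The fitness statistic ``omega`` is the maximum of ``MCO|r`` over every
admissible relative position.  Strands are aligned antiparallel: strand 1 is
written 5'->3' left to right and strand 2 is written 3'->5' left to right,
which is equivalent to looking for common substrings of strand 1 and the
reverse complement of strand 2.  ``omega`` may be achieved by several
distinct windows; all of them are enumerated.

The module also provides constrained sequence design (draw a random strand
with a prescribed ``omega`` against a given resource strand), FASTA I/O and
tabular export of overlap profiles.
"""
from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConstraintError, InputError

#: Watson-Crick complement of each canonical DNA base.
COMPLEMENT: Mapping[str, str] = {"A": "T", "T": "A", "C": "G", "G": "C"}

_BASES = frozenset(COMPLEMENT)

# The three oligomers of the reference predator/resource ecosystem: a 20-nt
# resource strand and two 50-mer predators, one with a weak maximum
# consecutive overlap with the resource (omega = 4) and one with a strong one
# (omega = 10).  All sequences 5'->3'.
RES_SEQ = "CGGTATTGGACCCTCGCATG"
P4_SEQ = "GGTGCGCGTGGCAAACGGGGCGTTGTGGGGCGTGCAGCGCTGACGGTCAA"
P10_SEQ = "GCGGTGCACGCAACGCCGGATGCGAGGGTGCTTGTTGCGAGGGCTGCTGG"


def _validate_seq(seq: str) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise InputError("empty sequence")
    for i, b in enumerate(seq):
        if b not in _BASES:
            hint = " (RNA is not supported)" if b == "U" else ""
            raise InputError(
                f"non-canonical base {b!r} at position {i}{hint}; "
                "only A/C/G/T are allowed"
            )
    return seq


@dataclass(frozen=True)
class Oligomer:
    """A named single-stranded DNA oligomer, stored 5'->3', 0-based."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _validate_seq(self.seq))

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def reverse_complement(self, name: str | None = None) -> "Oligomer":
        rc = self.seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        return Oligomer(name or f"{self.name}_rc", rc)

    def __str__(self) -> str:
        return self.seq


def as_oligomer(x: "Oligomer | str", name: str = "seq") -> Oligomer:
    """Coerce a raw string into an :class:`Oligomer` (validated)."""
    return x if isinstance(x, Oligomer) else Oligomer(name, x)


def complementary(b1: str, b2: str) -> bool:
    """True iff ``b1``/``b2`` form a canonical Watson-Crick pair.

    Only A/T and C/G pair; the relation is symmetric.  Non-canonical
    characters raise :class:`InputError` naming the offending symbol.
    """
    b1, b2 = b1.upper(), b2.upper()
    for b in (b1, b2):
        if b not in _BASES:
            raise InputError(f"non-canonical base {b!r}; only A/C/G/T pair")
    return COMPLEMENT[b1] == b2


def relative_positions(L: int, l: int) -> range:
    """Admissible relative positions for strand lengths ``L`` and ``l``.

    ``r`` is the rightward shift of strand 2's left end from strand 1's left
    end, strand 2 being written 3'->5' (antiparallel).  There are exactly
    ``L + l - 1`` admissible values: ``r in [-l+1, L-1]``.
    """
    if L < 1 or l < 1:
        raise InputError("strand lengths must be positive")
    return range(-l + 1, L)


@dataclass(frozen=True)
class OmegaWindow:
    """One maximal run realizing ``omega`` at relative position ``r``.

    ``start1``/``start2`` are 0-based 5'->3' indices of the run's first base
    on each strand; base ``start1 + k`` of strand 1 pairs with base
    ``start2 + (length - 1) - k`` of strand 2 (antiparallel register).
    """

    r: int
    start1: int
    start2: int
    length: int

    def strand1_span(self) -> tuple[int, int]:
        """Inclusive 5'->3' index range covered on strand 1."""
        return (self.start1, self.start1 + self.length - 1)

    def strand2_span(self) -> tuple[int, int]:
        """Inclusive 5'->3' index range covered on strand 2."""
        return (self.start2, self.start2 + self.length - 1)


@dataclass
class OverlapProfile:
    """MCO/TMO for a strand pair at every relative position, plus omega."""

    pair: tuple[Oligomer, Oligomer]
    mco_by_r: dict[int, int]
    tmo_by_r: dict[int, int]
    omega: int
    windows: list[OmegaWindow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Per-position table with columns ``r``, ``mco``, ``tmo``."""
        rs = sorted(self.mco_by_r)
        return pd.DataFrame(
            {
                "r": rs,
                "mco": [self.mco_by_r[r] for r in rs],
                "tmo": [self.tmo_by_r[r] for r in rs],
            }
        )

    def to_tsv(self) -> str:
        """Tab-separated per-position table; indices are 0-based."""
        buf = io.StringIO()
        buf.write(
            f"# omega profile for {self.pair[0].name} vs {self.pair[1].name}; "
            "r = shift of strand2 (3'->5') left end from strand1 left end; "
            "0-based indices\n"
        )
        self.to_frame().to_csv(buf, sep="\t", index=False)
        return buf.getvalue()

    def to_dict(self) -> dict:
        return {
            "strand1": self.pair[0].name,
            "strand2": self.pair[1].name,
            "omega": self.omega,
            "per_position": [
                {"r": r, "mco": self.mco_by_r[r], "tmo": self.tmo_by_r[r]}
                for r in sorted(self.mco_by_r)
            ],
            "windows": [
                {
                    "r": w.r,
                    "start1": w.start1,
                    "start2": w.start2,
                    "length": w.length,
                }
                for w in self.windows
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _match_vector(s1: str, s2_rev: str, r: int) -> tuple[int, np.ndarray]:
    """Complementarity mask over the overlap region at offset ``r``.

    ``s2_rev`` is strand 2 written 3'->5' (i.e. the reversed sequence).
    Returns the strand-1 index of the first overlapping column and a boolean
    array, one entry per overlapping column.
    """
    L, l = len(s1), len(s2_rev)
    lo = max(0, r)          # first strand-1 index in the overlap
    hi = min(L, r + l)      # one past the last
    a = np.frombuffer(s1[lo:hi].encode(), dtype=np.uint8)
    comp = np.frombuffer(
        s2_rev[lo - r : hi - r].translate(str.maketrans("ACGT", "TGCA")).encode(),
        dtype=np.uint8,
    )
    return lo, a == comp


def _runs(mask: np.ndarray) -> Iterator[tuple[int, int]]:
    """Yield (start, length) of each maximal run of True in ``mask``."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e] - idx[s] + 1)


def overlap_at(
    s1: Oligomer | str, s2: Oligomer | str, r: int
) -> tuple[int, int]:
    """(MCO, TMO) for the pair held at relative position ``r``.

    Raises :class:`InputError` when ``r`` is outside ``[-l+1, L-1]``.
    """
    s1, s2 = as_oligomer(s1, "s1"), as_oligomer(s2, "s2")
    L, l = len(s1), len(s2)
    if r not in relative_positions(L, l):
        raise InputError(
            f"relative position r={r} outside admissible range "
            f"[{-l + 1}, {L - 1}] for lengths L={L}, l={l}"
        )
    _, mask = _match_vector(s1.seq, s2.seq[::-1], r)
    tmo = int(mask.sum())
    mco = max((length for _, length in _runs(mask)), default=0)
    return mco, tmo


def profile(s1: Oligomer | str, s2: Oligomer | str) -> OverlapProfile:
    """Full overlap profile: per-position MCO/TMO, omega and its windows.

    ``omega = max_r MCO|r``; ``windows`` lists every maximal run of length
    omega across all positions, sorted by ``(r, start1)`` (the maximum can be
    degenerate).  The profile has exactly ``L + l - 1`` positions and is
    symmetric in omega: ``profile(a, b).omega == profile(b, a).omega``.
    """
    s1, s2 = as_oligomer(s1, "s1"), as_oligomer(s2, "s2")
    L, l = len(s1), len(s2)
    s2_rev = s2.seq[::-1]
    mco_by_r: dict[int, int] = {}
    tmo_by_r: dict[int, int] = {}
    runs_by_r: dict[int, list[tuple[int, int]]] = {}
    for r in relative_positions(L, l):
        lo, mask = _match_vector(s1.seq, s2_rev, r)
        tmo_by_r[r] = int(mask.sum())
        runs = [(lo + start, length) for start, length in _runs(mask)]
        runs_by_r[r] = runs
        mco_by_r[r] = max((length for _, length in runs), default=0)
    omega = max(mco_by_r.values())
    windows: list[OmegaWindow] = []
    if omega >= 1:
        for r in sorted(runs_by_r):
            for start1, length in runs_by_r[r]:
                if length == omega:
                    # reversed-strand column start1-r maps to 5'->3' index
                    # l-1-(start1-r); the run's last column is its start2.
                    start2 = l - (start1 - r) - length
                    windows.append(OmegaWindow(r, start1, start2, length))
        windows.sort(key=lambda w: (w.r, w.start1))
    return OverlapProfile((s1, s2), mco_by_r, tmo_by_r, omega, windows)


def omega(s1: Oligomer | str, s2: Oligomer | str) -> int:
    """Shorthand for ``profile(s1, s2).omega``."""
    return profile(s1, s2).omega


def omega_oracle(s1: Oligomer | str, s2: Oligomer | str) -> int:
    """Brute-force omega: longest common substring of s1 and revcomp(s2).

    Enumerates all substring start pairs directly; independent of
    :func:`profile` and used to cross-check it.
    """
    s1, s2 = as_oligomer(s1, "s1"), as_oligomer(s2, "s2")
    a = s1.seq
    b = s2.reverse_complement().seq
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            if k > best:
                best = k
    return best


def design_sequence(
    resource: Oligomer | str,
    L: int,
    omega_target: int,
    rng_seed: int,
    max_tries: int = 10_000,
    name: str | None = None,
) -> Oligomer:
    """Draw a random ``L``-mer whose omega against ``resource`` is exact.

    Strategy: embed the reverse complement of a random ``omega_target``-long
    window of the resource at a random position in a random background, then
    reject the draw unless the realized omega equals the target (the random
    background can create accidental longer or equal windows).  Deterministic
    for a given ``rng_seed``.

    Raises :class:`InputError` for unachievable targets and
    :class:`ConstraintError` when ``max_tries`` draws all fail.
    """
    resource = as_oligomer(resource, "resource")
    l = len(resource)
    if L < 1:
        raise InputError("designed length L must be positive")
    if not 1 <= omega_target <= min(L, l):
        raise InputError(
            f"omega_target={omega_target} not in [1, min(L, l)] = "
            f"[1, {min(L, l)}]: a run cannot exceed either strand"
        )
    rng = np.random.default_rng(rng_seed)
    bases = np.array(list("ACGT"))
    window_rc = None
    for _ in range(max_tries):
        w = int(rng.integers(0, l - omega_target + 1))
        window_rc = Oligomer(
            "w", resource.seq[w : w + omega_target]
        ).reverse_complement().seq
        background = rng.choice(bases, size=L)
        pos = int(rng.integers(0, L - omega_target + 1))
        background[pos : pos + omega_target] = list(window_rc)
        candidate = "".join(background)
        if profile(candidate, resource).omega == omega_target:
            return Oligomer(name or f"designed_w{omega_target}", candidate)
    raise ConstraintError(
        f"no {L}-mer with omega={omega_target} vs {resource.name!r} found in "
        f"{max_tries} tries; the omega constraint could not be satisfied"
    )


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path_or_handle) -> list[Oligomer]:
    """Read an oligomer set from FASTA; the header token is the name."""
    records = SeqIO.parse(path_or_handle, "fasta")
    return [Oligomer(rec.id, str(rec.seq)) for rec in records]


def write_fasta(oligomers: Iterable[Oligomer], path_or_handle) -> None:
    records = [
        SeqRecord(Seq(o.seq), id=o.name, description="") for o in oligomers
    ]
    SeqIO.write(records, path_or_handle, "fasta")


def omega_matrix(oligomers: Sequence[Oligomer]) -> pd.DataFrame:
    """Pairwise omega for every ordered pair (symmetric; diagonal is the
    inter-strand self-interaction of two copies of the same sequence)."""
    names = [o.name for o in oligomers]
    mat = pd.DataFrame(index=names, columns=names, dtype=int)
    for i, a in enumerate(oligomers):
        for b in oligomers[i:]:
            val = profile(a, b).omega
            mat.loc[a.name, b.name] = val
            mat.loc[b.name, a.name] = val
    return mat.astype(int)
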
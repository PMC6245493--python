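"""Synthetic homologous DNA pairs with controlled divergence.

The generator draws a uniform-random ancestor and derives a copy by
independent per-base substitutions (rate ``sub_rate``) and geometric-length
insertions/deletions (per-position event rate ``indel_rate``, mean length
``mean_indel_len``, insertion and deletion equiprobable).  That reproduces
the character of real homologous-chromosome comparisons at desk scale --
high identity with clustered gaps -- without any biological repeat or GC
structure, which the generator deliberately does not model.

Every edit is recorded so derived lengths and realized rates can be checked
exactly; a fixed seed yields byte-identical output everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, TextIO, Tuple

import numpy as np

from .core import DNA_ALPHABET, PlacementError, Sequence

_BASES = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class EditEvent:
    """One mutation applied to the ancestor: op in {sub, ins, del}.

    ``position`` is the 1-based ancestor coordinate the event applies at
    (insertions occur before that position); ``bases`` holds the new bases
    for sub/ins and the removed bases for del.
    """

    op: str
    position: int
    length: int
    bases: str


def _random_bases(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def generate_homolog_pair(
    length: int,
    sub_rate: float,
    indel_rate: float,
    mean_indel_len: float = 5.0,
    seed: int = 0,
) -> Tuple[Sequence, Sequence, List[EditEvent]]:
    """An ancestor sequence and a mutated copy, plus the exact edit record.

    The derived length equals ``length + inserted - deleted`` per the
    record.  Rates must lie in [0, 1); substitutions always change the base.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    for name, rate in (("sub_rate", sub_rate), ("indel_rate", indel_rate)):
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"{name} must be in [0, 1), got {rate}")
    if mean_indel_len < 1:
        raise ValueError("mean_indel_len must be >= 1")
    rng = np.random.default_rng(seed)
    ancestor = _random_bases(rng, length)
    events: List[EditEvent] = []
    out: List[str] = []
    i = 0
    while i < length:
        if indel_rate > 0.0 and rng.random() < indel_rate:
            ln = int(rng.geometric(1.0 / mean_indel_len))
            if rng.random() < 0.5:
                ins = _random_bases(rng, ln)
                events.append(EditEvent("ins", i + 1, ln, ins))
                out.append(ins)
            else:
                ln = min(ln, length - i)
                events.append(EditEvent("del", i + 1, ln, ancestor[i : i + ln]))
                i += ln
                continue
        base = ancestor[i]
        if sub_rate > 0.0 and rng.random() < sub_rate:
            alt = DNA_ALPHABET.replace(base, "")
            base = alt[int(rng.integers(0, 3))]
            events.append(EditEvent("sub", i + 1, 1, base))
        out.append(base)
        i += 1
    s0 = Sequence("ancestor", ancestor)
    s1 = Sequence("derived", "".join(out))
    return s0, s1, events


def plant_decoy_repeat(
    pair: Tuple[Sequence, Sequence],
    block_len: int,
    position: int,
    seed: int = 0,
) -> Tuple[Sequence, Sequence]:
    """Copy a block of S0 into S1 at ``position`` (0-based), off-diagonal.

    The pasted block perfectly matches a stretch of S0 far from the main
    homology diagonal, creating a high-scoring decoy region so that a border
    column's maximum need not lie on the optimal path (the scenario that
    makes speculative traceback mispredict).  The source block is drawn with
    ``seed`` at least ``block_len`` away from ``position``; a zero-length
    block is the identity.
    """
    s0, s1 = pair[0], pair[1]
    if block_len == 0:
        return s0, s1
    if block_len < 0:
        raise PlacementError("block_len must be >= 0")
    if position < 0 or position + block_len > len(s1):
        raise PlacementError("decoy block does not fit in S1")
    if block_len > len(s0):
        raise PlacementError("decoy block longer than S0")
    rng = np.random.default_rng(seed)
    candidates = [
        src
        for src in range(0, len(s0) - block_len + 1)
        if abs(src - position) >= block_len
    ]
    if not candidates:
        raise PlacementError("no off-diagonal source position available")
    src = int(candidates[int(rng.integers(0, len(candidates)))])
    block = s0.residues[src : src + block_len]
    residues = s1.residues[:position] + block + s1.residues[position + block_len :]
    return s0, Sequence(s1.id + "_decoy", residues)


def write_edit_record(events: List[EditEvent], fh: TextIO) -> None:
    fh.write("op\tposition\tlength\tbases\n")
    for ev in events:
        fh.write(f"{ev.op}\t{ev.position}\t{ev.length}\t{ev.bases}\n")
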
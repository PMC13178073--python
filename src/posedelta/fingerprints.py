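"""Circular (Morgan/ECFP-style) fingerprints and Tanimoto similarity.

The implementation is native and platform-stable: atom environments are
hashed with CRC32 over packed integer tuples, so identical graphs give
identical fingerprints on any machine. Initial atom invariants are
(atomic number, heavy degree, attached hydrogens, formal charge, ring
flag); each iteration rehashes an atom's identifier together with the
sorted (bond order, neighbour identifier) list, and environments covering
an already-seen bond set are deduplicated, as in standard ECFP generation.

Two similarity variants are provided: Tanimoto on the folded bitset
(|A&B|/|A|B|) and Tanimoto on the unfolded environment-count multisets
(sum-min over sum-max). The count variant is the default for reports: on
folded bitsets the dense, repetitive environments of fused polycyclic
scaffolds collide and truncate, which systematically deflates
triterpenoid-triterpenoid similarities.
"""

from __future__ import annotations

import struct
import zlib
from collections import Counter
from dataclasses import dataclass, field

from .core import LigandGraph
from .errors import PoseDeltaError, TopologyError

DEFAULT_RADIUS = 2
DEFAULT_NBITS = 2048


def _hash_ints(*values: int) -> int:
    """Stable 32-bit mix of a tuple of (possibly negative) integers."""
    masked = [v & 0xFFFFFFFF for v in values]
    return zlib.crc32(struct.pack(f">{len(masked)}I", *masked))


@dataclass(frozen=True)
class FingerprintProfile:
    bits: frozenset[int]  # on-bit positions after folding
    counts: dict[int, int]  # unfolded environment identifier -> multiplicity
    radius: int
    n_bits: int

    @property
    def n_on(self) -> int:
        return len(self.bits)


def morgan_fingerprint(graph: LigandGraph, radius: int = DEFAULT_RADIUS,
                       n_bits: int = DEFAULT_NBITS) -> FingerprintProfile:
    """Hashed circular fingerprint of a connected molecular graph."""
    if radius < 0 or n_bits < 1:
        raise PoseDeltaError("radius must be >= 0 and n_bits >= 1")
    if not graph.is_connected():
        raise TopologyError("fingerprints are defined for connected graphs only")

    n = graph.n_atoms
    ids = [
        _hash_ints(a.atomic_number, len(graph.neighbors[i]), a.n_hydrogens,
                   a.formal_charge, int(a.in_ring))
        for i, a in enumerate(graph.atoms)
    ]
    # bonds within the environment of each atom at the current iteration
    env_bonds: list[frozenset[int]] = [frozenset() for _ in range(n)]
    incident: list[set[int]] = [set() for _ in range(n)]
    bond_index = {}
    for b_idx, b in enumerate(graph.bonds):
        incident[b.i].add(b_idx)
        incident[b.j].add(b_idx)
        bond_index[(b.i, b.j)] = b_idx
        bond_index[(b.j, b.i)] = b_idx

    features = Counter(ids)  # iteration-0 environments, one per atom
    # the empty bond set is "seen" at iteration 0, so an environment that
    # fails to grow (isolated atom) contributes no duplicate feature
    seen_bond_sets: set[frozenset[int]] = {frozenset()}

    for it in range(1, radius + 1):
        new_ids = list(ids)
        new_env = list(env_bonds)
        round_features: list[tuple[int, frozenset[int]]] = []
        for i in range(n):
            nbrs = sorted(
                (int(order * 10), ids[j]) for j, order in graph.neighbors[i]
            )
            flat = [it, ids[i]]
            for code, nid in nbrs:
                flat.extend((code, nid))
            new_ids[i] = _hash_ints(*flat)
            cover = set(incident[i])
            for j, _ in graph.neighbors[i]:
                cover |= env_bonds[j]
                cover.add(bond_index[(i, j)])
            new_env[i] = frozenset(cover)
            round_features.append((new_ids[i], new_env[i]))
        ids, env_bonds = new_ids, new_env
        # keep one feature per distinct bond set, smallest identifier first
        for ident, cover in sorted(round_features):
            if cover in seen_bond_sets:
                continue
            seen_bond_sets.add(cover)
            features[ident] += 1

    bits = frozenset(ident % n_bits for ident in features)
    return FingerprintProfile(bits=bits, counts=dict(features),
                              radius=radius, n_bits=n_bits)


def tanimoto(a: FingerprintProfile, b: FingerprintProfile,
             weighted: bool = True) -> float:
    """Tanimoto similarity in [0, 1].

    ``weighted=True`` (default) compares the unfolded environment-count
    multisets; ``weighted=False`` compares the folded bitsets. Two empty
    fingerprints score 1.0 by convention.
    """
    if a.radius != b.radius:
        raise PoseDeltaError(f"fingerprint radii differ: {a.radius} vs {b.radius}")
    if not weighted and a.n_bits != b.n_bits:
        raise PoseDeltaError(f"bit lengths differ: {a.n_bits} vs {b.n_bits}")
    if weighted:
        keys = set(a.counts) | set(b.counts)
        if not keys:
            return 1.0
        num = sum(min(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys)
        den = sum(max(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys)
        return num / den
    union = a.bits | b.bits
    if not union:
        return 1.0
    return len(a.bits & b.bits) / len(union)


def similarity_matrix(profiles: dict[str, FingerprintProfile],
                      weighted: bool = True) -> dict[tuple[str, str], float]:
    """Pairwise Tanimoto over a labelled set of fingerprints."""
    names = sorted(profiles)
    out = {}
    for i, x in enumerate(names):
        for y in names[i:]:
            out[(x, y)] = tanimoto(profiles[x], profiles[y], weighted=weighted)
    return out
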
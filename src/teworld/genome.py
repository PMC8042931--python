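"""Spatially explicit chromosome model.

The genome is a linear sequence of segments laid out on 0-based, half-open
coordinates: the genes in index order, then one intergenic block, with TE
copies spliced in wherever they inserted.  Every insertion shifts downstream
coordinates by the TE length, so total length grows with TE replication —
the "TE engineering" substrate: accumulated TE DNA dilutes the genic target.

Segments are ``(kind, ident, length)`` tuples.  A gene or a TE may be split
into several segments by nested insertions; all parts share the same ident.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

GENE = "G"
INTER = "I"
TE = "T"


class SiteKind(Enum):
    GENIC = "GENIC"
    INTERGENIC = "INTERGENIC"
    WITHIN_TE = "WITHIN_TE"


@dataclass(frozen=True)
class SiteClass:
    """Classification of a single base-pair position."""

    kind: SiteKind
    gene_index: Optional[int] = None
    te_id: Optional[int] = None


@dataclass
class TECopy:
    """One TE copy resident in a genome.

    ``nested_in`` records the te_id of a host copy when the insertion landed
    inside another TE; inactive copies are dead DNA and never transpose.
    """

    te_id: int
    active: bool = True
    nested_in: Optional[int] = None


class GenomeError(ValueError):
    pass


class Genome:
    """A host chromosome: fixed genes, an intergenic block, and TE copies.

    Mutating operations keep an exact length ledger; ``total_length`` always
    equals the sum of segment lengths (checked by :meth:`check_invariants`).
    """

    __slots__ = (
        "gene_count",
        "gene_length",
        "te_length",
        "intergenic_length",
        "segments",
        "tes",
        "disrupted_genes",
        "_next_te_id",
        "_starts",
        "_genic_bp",
    )

    def __init__(self, gene_count: int, gene_length: int, te_length: int,
                 intergenic_length: int):
        if gene_count <= 0 or gene_length <= 0 or te_length <= 0:
            raise GenomeError("gene_count, gene_length and te_length must be positive")
        if intergenic_length < 0:
            raise GenomeError("intergenic_length must be non-negative")
        self.gene_count = gene_count
        self.gene_length = gene_length
        self.te_length = te_length
        self.intergenic_length = intergenic_length
        self.segments: list[tuple[str, int, int]] = [
            (GENE, i, gene_length) for i in range(gene_count)
        ]
        self.segments.append((INTER, 0, intergenic_length))
        self.tes: dict[int, TECopy] = {}
        self.disrupted_genes: set[int] = set()
        self._next_te_id = 0
        self._starts: Optional[np.ndarray] = None
        self._genic_bp = gene_count * gene_length

    # -- bookkeeping -------------------------------------------------------

    @property
    def total_length(self) -> int:
        return self._genic_bp + self.nongenic_bp

    @property
    def genic_bp(self) -> int:
        return self._genic_bp

    @property
    def nongenic_bp(self) -> int:
        return self.intergenic_length + len(self.tes) * self.te_length

    @property
    def n_tes(self) -> int:
        return len(self.tes)

    @property
    def n_active_tes(self) -> int:
        return sum(1 for t in self.tes.values() if t.active)

    def active_te_ids(self) -> list[int]:
        return [i for i, t in self.tes.items() if t.active]

    def _segment_starts(self) -> np.ndarray:
        if self._starts is None:
            lengths = np.fromiter((s[2] for s in self.segments), dtype=np.int64,
                                  count=len(self.segments))
            self._starts = np.concatenate(([0], np.cumsum(lengths)))
        return self._starts

    def copy(self) -> "Genome":
        """Cheap structural copy (segments are immutable tuples)."""
        g = Genome.__new__(Genome)
        g.gene_count = self.gene_count
        g.gene_length = self.gene_length
        g.te_length = self.te_length
        g.intergenic_length = self.intergenic_length
        g.segments = list(self.segments)
        g.tes = {i: TECopy(t.te_id, t.active, t.nested_in)
                 for i, t in self.tes.items()}
        g.disrupted_genes = set(self.disrupted_genes)
        g._next_te_id = self._next_te_id
        g._starts = self._starts
        g._genic_bp = self._genic_bp
        return g

    def check_invariants(self) -> None:
        assert sum(s[2] for s in self.segments) == self.total_length
        assert sum(s[2] for s in self.segments if s[0] == GENE) == self._genic_bp

    # -- queries -----------------------------------------------------------

    def classify_site(self, position: int) -> SiteClass:
        """Classify the region containing a base-pair position."""
        if not 0 <= position < self.total_length:
            raise IndexError(
                f"position {position} outside genome of length {self.total_length}")
        starts = self._segment_starts()
        idx = int(np.searchsorted(starts, position, side="right")) - 1
        # skip zero-length segments sharing the boundary
        while self.segments[idx][2] == 0:
            idx += 1
        kind, ident, _ = self.segments[idx]
        if kind == GENE:
            return SiteClass(SiteKind.GENIC, gene_index=ident)
        if kind == TE:
            return SiteClass(SiteKind.WITHIN_TE, te_id=ident)
        return SiteClass(SiteKind.INTERGENIC)

    def sample_insertion_site(self, insertion_bias: float,
                              rng: np.random.Generator) -> int:
        """Draw an insertion position under genic insertion bias.

        ``insertion_bias`` is the relative per-bp weight of genic DNA:
        1 means uniform over all bp, 0 means genic DNA is never hit, and
        intermediate values bias insertions away from genes, so
        P(GENIC) = bias*G / (bias*G + NG).
        """
        if not 0.0 <= insertion_bias <= 1.0:
            raise GenomeError("insertion_bias must lie in [0, 1]")
        g_bp = self._genic_bp
        ng_bp = self.nongenic_bp
        w_gen = insertion_bias * g_bp
        total = w_gen + ng_bp
        if total <= 0:
            raise GenomeError("genome has no insertable DNA under this bias")
        genic = rng.random() * total < w_gen
        if genic:
            offset = int(rng.integers(g_bp))
            want = GENE
        else:
            offset = int(rng.integers(ng_bp))
            want = None  # any non-genic segment
        pos = 0
        for kind, _, length in self.segments:
            hit = (kind == GENE) if want == GENE else (kind != GENE)
            if hit:
                if offset < length:
                    return pos + offset
                offset -= length
            pos += length
        raise AssertionError("offset exhausted segment walk")  # pragma: no cover

    # -- mutation ----------------------------------------------------------

    def new_te_id(self) -> int:
        i = self._next_te_id
        self._next_te_id = i + 1
        return i

    def insert_te(self, position: int, new_te_id: Optional[int] = None,
                  active: bool = True) -> int:
        """Splice a new TE copy in front of ``position``; returns its te_id.

        Downstream coordinates shift by ``te_length``.  A genic landing marks
        the gene disrupted (permanently for this lineage); a landing inside
        another TE records nesting and carries no fitness bookkeeping here.
        """
        if not 0 <= position < self.total_length:
            raise IndexError(
                f"position {position} outside genome of length {self.total_length}")
        if new_te_id is None:
            new_te_id = self.new_te_id()
        elif new_te_id in self.tes:
            raise GenomeError(f"duplicate te_id {new_te_id}")
        else:
            self._next_te_id = max(self._next_te_id, new_te_id + 1)

        starts = self._segment_starts()
        idx = int(np.searchsorted(starts, position, side="right")) - 1
        while self.segments[idx][2] == 0:
            idx += 1
        kind, ident, length = self.segments[idx]
        left = position - int(starts[idx])
        nested_in = None
        if kind == GENE:
            self.disrupted_genes.add(ident)
        elif kind == TE:
            nested_in = ident

        new_seg = (TE, new_te_id, self.te_length)
        if left == 0:
            self.segments.insert(idx, new_seg)
        elif left == length:  # pragma: no cover - half-open guard
            self.segments.insert(idx + 1, new_seg)
        else:
            self.segments[idx:idx + 1] = [
                (kind, ident, left), new_seg, (kind, ident, length - left)]
        self.tes[new_te_id] = TECopy(new_te_id, active=active, nested_in=nested_in)
        self._starts = None
        return new_te_id

    def remove_te(self, te_id: int) -> None:
        """Excise a TE copy; its bp leave the genome and downstream
        coordinates shift back.  Copies nested inside it stay in place,
        re-anchored to the surrounding region."""
        if te_id not in self.tes:
            raise KeyError(f"unknown te_id {te_id}")
        kept = []
        for seg in self.segments:
            if seg[0] == TE and seg[1] == te_id:
                continue
            kept.append(seg)
        # merge adjacent parts of the same region split by the removed copy
        merged: list[tuple[str, int, int]] = []
        for seg in kept:
            if merged and merged[-1][0] == seg[0] and merged[-1][1] == seg[1]:
                merged[-1] = (seg[0], seg[1], merged[-1][2] + seg[2])
            else:
                merged.append(seg)
        self.segments = merged
        del self.tes[te_id]
        for t in self.tes.values():
            if t.nested_in == te_id:
                t.nested_in = None
        self._starts = None

    def deactivate_te(self, te_id: int) -> None:
        """Kill a TE copy in place: it stops transposing but its bp remain
        as non-genic DNA (the default death semantics)."""
        self.tes[te_id].active = False

    def te_position(self, te_id: int) -> int:
        """Current start coordinate of a copy's first segment."""
        starts = self._segment_starts()
        for i, seg in enumerate(self.segments):
            if seg[0] == TE and seg[1] == te_id:
                return int(starts[i])
        raise KeyError(f"unknown te_id {te_id}")

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "gene_count": self.gene_count,
            "gene_length": self.gene_length,
            "te_length": self.te_length,
            "intergenic_length": self.intergenic_length,
            "segments": self.segments,
            "tes": [{"te_id": t.te_id, "active": t.active,
                     "nested_in": t.nested_in} for t in self.tes.values()],
            "disrupted_genes": sorted(self.disrupted_genes),
        })


def new_genome(gene_count: int, gene_length: int = 1000, te_length: int = 1000,
               initial_te_count: int = 0, intergenic_length: Optional[int] = None,
               rng: Optional[np.random.Generator] = None) -> Genome:
    """Build a fresh genome with ``initial_te_count`` active TE copies placed
    uniformly at random in the intergenic block.

    ``intergenic_length`` defaults to 10% of the genic bp.
    """
    if initial_te_count < 0:
        raise GenomeError("initial_te_count must be >= 0")
    if intergenic_length is None:
        intergenic_length = gene_count * gene_length // 10
    g = Genome(gene_count, gene_length, te_length, intergenic_length)
    if initial_te_count:
        if rng is None:
            raise GenomeError("rng required to place initial TEs")
        if intergenic_length <= 0:
            raise GenomeError("cannot place initial TEs without intergenic DNA")
        base = gene_count * gene_length
        for _ in range(initial_te_count):
            pos = base + int(rng.integers(g.intergenic_length))
            # anchor inside the intergenic block, never inside a prior copy
            while g.classify_site(pos).kind is not SiteKind.INTERGENIC:
                pos = base + int(rng.integers(g.intergenic_length))
            g.insert_te(pos)
    return g
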
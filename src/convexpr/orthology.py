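"""1:1 single-copy orthologue inference via reciprocal best hits.

Per species pair, the best hit of a query is the record with the lowest
E-value, ties broken by the highest bit score, then by lexicographically
smallest subject id — a deterministic total order under input permutation.
A pair (a, b) is an RBH iff each is the other's best hit. Across more than
two species, a row of the orthologue map is a tuple with one gene per
species such that EVERY pairwise link in the tuple is an RBH pair (a clique,
not a transitive chain), which guarantees single-copy 1:1 semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io_formats import GeneRecord, HitRecord

__all__ = [
    "OrthologueMap",
    "select_longest_isoform",
    "best_hits",
    "reciprocal_best_hits",
    "one_to_one_orthologues",
    "write_orthologue_map",
    "read_orthologue_map",
]


@dataclass
class OrthologueMap:
    """1:1 gene correspondence across species; one orthogroup per row."""

    species_ids: list[str]
    rows: list[tuple[str, ...]]
    tissue: str = ""

    def __post_init__(self) -> None:
        for row in self.rows:
            if len(row) != len(self.species_ids):
                raise ValidationError(
                    f"orthologue row {row} does not cover all species"
                )
        for j in range(len(self.species_ids)):
            col = [row[j] for row in self.rows]
            if len(set(col)) != len(col):
                raise ValidationError(
                    f"gene appears in more than one orthologue row for "
                    f"species {self.species_ids[j]}"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.species_ids))


def select_longest_isoform(records: list[GeneRecord]) -> dict[str, str]:
    """Pick one representative isoform per gene: maximal protein length,
    ties broken by lexicographically smallest isoform id."""
    if not records:
        raise ValidationError("empty gene record list")
    best: dict[str, GeneRecord] = {}
    for rec in records:
        cur = best.get(rec.gene_id)
        if (
            cur is None
            or rec.protein_length > cur.protein_length
            or (rec.protein_length == cur.protein_length and rec.isoform_id < cur.isoform_id)
        ):
            best[rec.gene_id] = rec
    return {gene_id: rec.isoform_id for gene_id, rec in best.items()}


def _hit_key(rec: HitRecord) -> tuple[float, float, str]:
    # smaller is better: (evalue, -bit_score, subject_id)
    return (rec.evalue, -rec.bit_score, rec.subject_id)


def best_hits(hits: list[HitRecord]) -> dict[str, str]:
    """Best subject per query under the (evalue, -bit_score, subject_id) order."""
    best: dict[str, HitRecord] = {}
    for rec in hits:
        cur = best.get(rec.query_id)
        if cur is None or _hit_key(rec) < _hit_key(cur):
            best[rec.query_id] = rec
    return {q: rec.subject_id for q, rec in best.items()}


def reciprocal_best_hits(
    hits_ab: list[HitRecord], hits_ba: list[HitRecord]
) -> set[tuple[str, str]]:
    """Pairs (a, b) with b the best hit of a in hits_ab and vice versa."""
    best_ab = best_hits(hits_ab)
    best_ba = best_hits(hits_ba)
    return {
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    }


def one_to_one_orthologues(
    rbh_sets: dict[tuple[str, str], set[tuple[str, str]]],
    species_ids: list[str],
    tissue: str = "",
) -> OrthologueMap:
    """Intersect pairwise RBH sets into 1:1 orthogroups across all species.

    ``rbh_sets`` maps an ordered species pair (s_i, s_j) to the RBH pairs
    (gene_in_s_i, gene_in_s_j); each unordered pair must be present under
    exactly one orientation. A row is emitted iff a full clique of RBH links
    exists among its genes. Because best hits are unique per query, distinct
    rows can never share a gene.
    """
    if len(species_ids) < 2:
        raise ConfigurationError("need at least 2 species")
    # normalise to partner maps keyed by ordered species pair, both directions
    partner: dict[tuple[str, str], dict[str, str]] = {}
    covered: set[frozenset[str]] = set()
    for (sa, sb), pairs in rbh_sets.items():
        if sa not in species_ids or sb not in species_ids:
            raise ConfigurationError(f"unknown species in RBH pair ({sa},{sb})")
        covered.add(frozenset((sa, sb)))
        fwd = partner.setdefault((sa, sb), {})
        rev = partner.setdefault((sb, sa), {})
        for a, b in pairs:
            if a in fwd or b in rev:
                raise ValidationError(
                    f"gene with two RBH partners within pair ({sa},{sb})"
                )
            fwd[a] = b
            rev[b] = a
    for sa, sb in combinations(species_ids, 2):
        if frozenset((sa, sb)) not in covered:
            raise ConfigurationError(f"missing RBH set for species pair ({sa},{sb})")

    anchor = species_ids[0]
    others = species_ids[1:]
    rows: list[tuple[str, ...]] = []
    anchor_genes = sorted(partner.get((anchor, others[0]), {}))
    for g0 in anchor_genes:
        tup = [g0]
        ok = True
        for sp in others:
            g = partner[(anchor, sp)].get(g0)
            if g is None:
                ok = False
                break
            tup.append(g)
        if not ok:
            continue
        # clique check among the non-anchor members
        for (i, sa), (j, sb) in combinations(enumerate(species_ids), 2):
            if partner[(sa, sb)].get(tup[i]) != tup[j]:
                ok = False
                break
        if ok:
            rows.append(tuple(tup))
    return OrthologueMap(species_ids=list(species_ids), rows=rows, tissue=tissue)


def write_orthologue_map(omap: OrthologueMap, path) -> None:
    omap.to_frame().to_csv(path, sep="\t", index=False)


def read_orthologue_map(path, tissue: str = "") -> OrthologueMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return OrthologueMap(
        species_ids=list(df.columns),
        rows=[tuple(r) for r in df.itertuples(index=False)],
        tissue=tissue,
    )
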
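"""Gene-family (homolog cluster) tables: readers, species attachment,
the terminal-singleton filter and annotation transfer.

Clusters arrive in one of two dialects: the MMseqs2 ``createtsv`` two-column
form (representative TAB member, one pair per line) or the MCL form (one
cluster per line, members tab-separated).  A protein belongs to exactly one
family within one clustering run; a run is tagged with the alignment-coverage
cutoff (*c* value) that produced it.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

log = logging.getLogger(__name__)

#: Reserved pseudo-term for families with no transferred annotation.  Keeping
#: them under a sentinel term lets unannotated families take part in the
#: enrichment contingency totals and be tested themselves.
NA_TERM = "NA"


class FamilyError(ValueError):
    """Base class for family-table errors."""


class ClusterParseError(FamilyError):
    pass


class ClusterValidationError(FamilyError):
    pass


@dataclass(frozen=True)
class FamilyTable:
    """Cluster membership plus (optionally) per-protein species.

    ``members`` maps family id -> member protein ids (order preserved from
    input).  Species sets ("taxonomic composition") become available after
    :func:`attach_species`.
    """

    members: dict[str, tuple[str, ...]]
    species_of: Optional[dict[str, str]] = None
    source: str = "unknown"
    c_value: Optional[float] = None

    @property
    def family_ids(self) -> tuple[str, ...]:
        return tuple(self.members)

    @property
    def n_families(self) -> int:
        return len(self.members)

    @property
    def n_proteins(self) -> int:
        return sum(len(m) for m in self.members.values())

    def proteins(self, fam: str) -> tuple[str, ...]:
        return self.members[fam]

    def species_set(self, fam: str) -> frozenset[str]:
        if self.species_of is None:
            raise FamilyError("species not attached; call attach_species first")
        return frozenset(self.species_of[p] for p in self.members[fam])

    def to_frame(self, annotations: Optional["AnnotationMap"] = None) -> pd.DataFrame:
        """Normalised table: family_id, n_proteins, n_species, species_list, terms."""
        rows = []
        for fam, prots in self.members.items():
            sp = sorted(self.species_set(fam)) if self.species_of is not None else []
            terms = ""
            if annotations is not None:
                terms = ",".join(sorted(annotations.family_terms.get(fam, frozenset())))
            rows.append(
                {
                    "family_id": fam,
                    "n_proteins": len(prots),
                    "n_species": len(sp),
                    "species_list": ",".join(sp),
                    "terms": terms,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnnotationMap:
    """Per-protein and per-family functional terms (COG letters or GO ids).

    ``mode`` records the transfer rule used: ``"any"`` (a term carried by any
    member annotates the family) or ``"fraction"`` (carried by >= 50% of
    member proteins, unannotated members counted in the denominator).
    """

    protein_terms: dict[str, frozenset[str]]
    family_terms: dict[str, frozenset[str]]
    mode: str = "any"

    def terms_tested(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.family_terms.values():
            out |= t
        return frozenset(out)


def _read_tsv_rows(path_or_lines) -> Iterable[tuple[int, list[str]]]:
    if isinstance(path_or_lines, (str, Path)):
        fh = open(path_or_lines, newline="")
        close = True
    else:
        fh = path_or_lines
        close = False
    try:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            yield lineno, row
    finally:
        if close:
            fh.close()


def read_mmseqs_clusters(path_or_lines, source: str = "mmseqs",
                         c_value: Optional[float] = None) -> FamilyTable:
    """Read MMseqs2 ``createtsv`` output: representative TAB member per line.

    Families are keyed by the representative id.  A representative missing its
    self-row is tolerated with a warning (some exports omit it); a member
    appearing under two representatives is an error.
    """
    members: dict[str, list[str]] = {}
    owner: dict[str, str] = {}
    self_seen: set[str] = set()
    for lineno, row in _read_tsv_rows(path_or_lines):
        if len(row) != 2:
            raise ClusterParseError(
                f"line {lineno}: expected 2 tab-separated fields, got {len(row)}"
            )
        rep, member = row[0].strip(), row[1].strip()
        if not rep or not member:
            raise ClusterParseError(f"line {lineno}: empty field")
        if member in owner and owner[member] != rep:
            raise ClusterValidationError(
                f"protein {member!r} assigned to two clusters "
                f"({owner[member]!r} and {rep!r})"
            )
        if member == rep:
            self_seen.add(rep)
        if member not in owner:
            owner[member] = rep
            members.setdefault(rep, []).append(member)
    for rep in members:
        if rep not in self_seen:
            log.warning("representative %r has no self-row; keeping cluster", rep)
    return FamilyTable(
        members={k: tuple(v) for k, v in members.items()},
        source=source,
        c_value=c_value,
    )


def read_mcl_clusters(path_or_lines, source: str = "mcl",
                      c_value: Optional[float] = None) -> FamilyTable:
    """Read MCL output: one cluster per line, members tab-separated.

    Families are keyed ``MCL<line number>``.  Duplicates within a line are
    deduplicated with a warning; duplicates across lines are an error.
    """
    members: dict[str, tuple[str, ...]] = {}
    owner: dict[str, str] = {}
    for lineno, row in _read_tsv_rows(path_or_lines):
        fam = f"MCL{lineno}"
        seen_here: list[str] = []
        for tok in (t.strip() for t in row):
            if not tok:
                continue
            if tok in seen_here:
                log.warning("line %d: duplicate member %r within cluster, deduplicated",
                            lineno, tok)
                continue
            if tok in owner:
                raise ClusterValidationError(
                    f"protein {tok!r} appears in clusters {owner[tok]!r} and {fam!r}"
                )
            owner[tok] = fam
            seen_here.append(tok)
        if seen_here:
            members[fam] = tuple(seen_here)
    return FamilyTable(members=members, source=source, c_value=c_value)


def read_species_map(path_or_lines) -> dict[str, str]:
    """Two-column TSV protein -> species."""
    out: dict[str, str] = {}
    for lineno, row in _read_tsv_rows(path_or_lines):
        if len(row) != 2:
            raise ClusterParseError(
                f"line {lineno}: species map needs 2 columns, got {len(row)}"
            )
        out[row[0].strip()] = row[1].strip()
    return out


def attach_species(
    fams: FamilyTable,
    mapping: Optional[Mapping[str, str]] = None,
    convention: str = "map",
    known_species: Optional[Iterable[str]] = None,
) -> FamilyTable:
    """Resolve every member protein to a species.

    ``convention="map"`` uses an explicit protein->species mapping;
    ``convention="prefix"`` takes the text before the first ``|`` of the
    protein id (the ``species|protein`` naming scheme).  With
    ``known_species`` given (e.g. the tree's leaf names), resolved species
    are checked against it.
    """
    species_of: dict[str, str] = {}
    offenders: list[str] = []
    known = set(known_species) if known_species is not None else None
    for prots in fams.members.values():
        for p in prots:
            if convention == "prefix":
                sp = p.split("|", 1)[0] if "|" in p else ""
            elif convention == "map":
                if mapping is None:
                    raise FamilyError('convention="map" requires a mapping')
                sp = mapping.get(p, "")
            else:
                raise FamilyError(f"unknown species convention {convention!r}")
            if not sp or (known is not None and sp not in known):
                offenders.append(p)
            else:
                species_of[p] = sp
    if offenders:
        shown = ", ".join(repr(p) for p in offenders[:10])
        more = f" (+{len(offenders) - 10} more)" if len(offenders) > 10 else ""
        raise ClusterValidationError(
            f"{len(offenders)} proteins with unresolvable species: {shown}{more}"
        )
    return replace(fams, species_of=species_of)


def drop_terminal_singletons(fams: FamilyTable) -> FamilyTable:
    """Remove species-specific clusters with fewer than two member proteins.

    A single-species cluster sits in that species' terminal phylostratum on
    its own lineage and on no other, so the per-lineage "at least two cluster
    members in the terminal phylostratum" rule reduces to this global filter.
    Multi-species families and single-species families with >= 2 paralogs are
    kept unchanged; the filter is idempotent.
    """
    if fams.species_of is None:
        raise FamilyError("species must be attached before filtering")
    kept = {
        fam: prots
        for fam, prots in fams.members.items()
        if not (len(fams.species_set(fam)) == 1 and len(prots) < 2)
    }
    return replace(fams, members=kept)


def read_annotations(path_or_lines) -> dict[str, frozenset[str]]:
    """Protein->terms TSV: protein TAB comma-separated terms (one row each)."""
    out: dict[str, frozenset[str]] = {}
    for lineno, row in _read_tsv_rows(path_or_lines):
        if len(row) < 1:
            continue
        prot = row[0].strip()
        terms = frozenset(
            t.strip() for t in (row[1] if len(row) > 1 else "").split(",") if t.strip()
        )
        out[prot] = out.get(prot, frozenset()) | terms
    return out


def transfer_annotations(
    fams: FamilyTable,
    protein_terms: Mapping[str, frozenset[str]],
    mode: str = "any",
) -> AnnotationMap:
    """Transfer per-protein terms to whole families.

    ``mode="any"``: the family carries the union of its members' terms.
    ``mode="fraction"``: the family carries a term only if >= 50% of its
    member proteins (annotated or not) carry it; the threshold is inclusive.
    Families left with no terms receive the reserved pseudo-term ``NA``.
    """
    if mode not in ("any", "fraction"):
        raise FamilyError(f"unknown transfer mode {mode!r}")
    prot_terms = {p: frozenset(t) for p, t in protein_terms.items()}
    fam_terms: dict[str, frozenset[str]] = {}
    for fam, prots in fams.members.items():
        if mode == "any":
            acc: set[str] = set()
            for p in prots:
                acc |= prot_terms.get(p, frozenset())
            terms = frozenset(acc)
        else:
            counts: dict[str, int] = {}
            for p in prots:
                for t in prot_terms.get(p, frozenset()):
                    counts[t] = counts.get(t, 0) + 1
            half = len(prots) / 2.0
            terms = frozenset(t for t, c in counts.items() if c >= half)
        fam_terms[fam] = terms if terms else frozenset((NA_TERM,))
    return AnnotationMap(protein_terms=prot_terms, family_terms=fam_terms, mode=mode)
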
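"""Per-genome pathway presence calls from homology hits.

A pathway is a boolean grammar over gene-family literals, e.g. the default
minimum viable gud/gar pathway ``(gudD|garD)&(gudL|garL)&garR``: a genome
needs a glucarate/galactarate dehydratase, a 5-KDG aldolase (either the GarL
or the DapA-like GudL form) and the TSA reductase GarR.  The glycerate kinase
garK is carried as an *excluded* family: its hits are reported but never
affect the verdict, because kinases are recruited independently and do not
co-evolve with the rest of the cluster.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from gudgar.profsearch import HomologyHit

DEFAULT_GRAMMAR = "(gudD|garD)&(gudL|garL)&garR"
DEFAULT_EXCLUDED = frozenset({"garK"})


# ---------------------------------------------------------------------------
# grammar


class _Expr:
    def evaluate(self, present: set[str]) -> bool:
        raise NotImplementedError

    def literals(self) -> set[str]:
        raise NotImplementedError


@dataclass(frozen=True)
class _Lit(_Expr):
    name: str

    def evaluate(self, present: set[str]) -> bool:
        return self.name in present

    def literals(self) -> set[str]:
        return {self.name}


@dataclass(frozen=True)
class _Bin(_Expr):
    op: str  # "&" or "|"
    left: _Expr
    right: _Expr

    def evaluate(self, present: set[str]) -> bool:
        if self.op == "&":
            return self.left.evaluate(present) and self.right.evaluate(present)
        return self.left.evaluate(present) or self.right.evaluate(present)

    def literals(self) -> set[str]:
        return self.left.literals() | self.right.literals()


_TOKEN = re.compile(r"\s*([()&|]|[A-Za-z0-9_.\-]+)")


def _tokenize(expr: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if m is None:
            if expr[pos:].strip():
                raise ValueError(f"bad character in grammar at offset {pos}: {expr[pos]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_grammar_expression(expr: str) -> _Expr:
    """Recursive-descent parser for '&'/'|' expressions with parentheses.

    '&' binds tighter than '|'.
    """
    tokens = _tokenize(expr)
    idx = 0

    def peek() -> str | None:
        return tokens[idx] if idx < len(tokens) else None

    def take() -> str:
        nonlocal idx
        tok = tokens[idx]
        idx += 1
        return tok

    def parse_or() -> _Expr:
        node = parse_and()
        while peek() == "|":
            take()
            node = _Bin("|", node, parse_and())
        return node

    def parse_and() -> _Expr:
        node = parse_atom()
        while peek() == "&":
            take()
            node = _Bin("&", node, parse_atom())
        return node

    def parse_atom() -> _Expr:
        tok = peek()
        if tok is None:
            raise ValueError("unexpected end of grammar expression")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ValueError("missing closing parenthesis in grammar")
            take()
            return node
        if tok in ("&", "|", ")"):
            raise ValueError(f"unexpected {tok!r} in grammar expression")
        return _Lit(take())

    node = parse_or()
    if idx != len(tokens):
        raise ValueError(f"trailing tokens in grammar: {tokens[idx:]}")
    return node


@dataclass
class PathwayGrammar:
    """A boolean pathway rule plus families annotated as verdict-neutral."""

    expression: _Expr
    excluded_families: frozenset[str] = DEFAULT_EXCLUDED
    source: str = DEFAULT_GRAMMAR

    @classmethod
    def from_string(
        cls, expr: str = DEFAULT_GRAMMAR, excluded: Iterable[str] = DEFAULT_EXCLUDED
    ) -> "PathwayGrammar":
        parsed = parse_grammar_expression(expr)
        excluded = frozenset(excluded)
        overlap = parsed.literals() & excluded
        if overlap:
            raise ValueError(f"excluded families appear in the grammar: {sorted(overlap)}")
        return cls(expression=parsed, excluded_families=excluded, source=expr)

    def families(self) -> set[str]:
        return self.expression.literals()

    def evaluate(self, present: Iterable[str]) -> bool:
        return self.expression.evaluate(set(present))


# ---------------------------------------------------------------------------
# calls


@dataclass
class PathwayCall:
    genome_id: str
    satisfied: bool
    best_hits: dict[str, HomologyHit]  # family_id -> hit (excluded families included)
    missing_families: frozenset[str]


def best_hits_per_family(
    hits: Iterable[HomologyHit],
) -> dict[tuple[str, str], HomologyHit]:
    """Keep one hit per (genome, family): lowest E-value, ties broken by
    higher raw score, then lexicographically smallest locus_tag."""
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in hits:
        key = (h.genome_id, h.family_id)
        cur = best.get(key)
        if cur is None or (h.e_value, -h.raw_score, h.locus_tag) < (
            cur.e_value,
            -cur.raw_score,
            cur.locus_tag,
        ):
            best[key] = h
    return best


def call_pathway(
    genome_id: str,
    genome_hits: Mapping[str, HomologyHit],
    grammar: PathwayGrammar,
) -> PathwayCall:
    """Evaluate the grammar for one genome over best-hit-reduced hits.

    *genome_hits* maps family_id -> best hit.  Excluded families never affect
    the verdict but stay in ``best_hits`` for reporting.
    """
    present = set(genome_hits) - grammar.excluded_families
    satisfied = grammar.evaluate(present)
    missing = frozenset(grammar.families() - present)
    return PathwayCall(
        genome_id=genome_id,
        satisfied=satisfied,
        best_hits=dict(genome_hits),
        missing_families=missing,
    )


def call_all(
    hits: Iterable[HomologyHit], grammar: PathwayGrammar, genome_ids: Iterable[str]
) -> dict[str, PathwayCall]:
    """Best-hit-reduce *hits* and call every genome in *genome_ids*."""
    best = best_hits_per_family(hits)
    per_genome: dict[str, dict[str, HomologyHit]] = {}
    for (genome, family), hit in best.items():
        per_genome.setdefault(genome, {})[family] = hit
    return {
        g: call_pathway(g, per_genome.get(g, {}), grammar) for g in genome_ids
    }


# ---------------------------------------------------------------------------
# prevalence


@dataclass(frozen=True)
class PrevalenceRow:
    species_id: str
    n_genomes: int
    n_with_pathway: int


def prevalence(
    calls: Mapping[str, PathwayCall], species_map: Mapping[str, str]
) -> list[PrevalenceRow]:
    """Per-species genome counts and pathway-positive counts, sorted by species."""
    missing = [g for g in calls if g not in species_map]
    if missing:
        raise ValueError(f"genome(s) without species assignment: {', '.join(sorted(missing))}")
    tally: dict[str, list[int]] = {}
    for genome, call in calls.items():
        row = tally.setdefault(species_map[genome], [0, 0])
        row[0] += 1
        row[1] += int(call.satisfied)
    return [
        PrevalenceRow(species_id=sp, n_genomes=n, n_with_pathway=k)
        for sp, (n, k) in sorted(tally.items())
    ]


# ---------------------------------------------------------------------------
# gene catalog export


def export_catalog(
    calls: Mapping[str, PathwayCall],
    nt_seqs: Mapping[str, Mapping[str, str]],
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Nucleotide catalog of every best-hit gene of every pathway-positive genome.

    *nt_seqs* maps genome_id -> {locus_tag: nucleotide sequence}.  Returns
    (fasta_records, gene_to_family) where fasta headers are
    "genome|locus|family".
    """
    records: list[tuple[str, str]] = []
    mapping: list[tuple[str, str]] = []
    for genome in sorted(calls):
        call = calls[genome]
        if not call.satisfied:
            continue
        for family in sorted(call.best_hits):
            hit = call.best_hits[family]
            seqs = nt_seqs.get(genome, {})
            if hit.locus_tag not in seqs:
                raise ValueError(
                    f"no nucleotide sequence for {genome}/{hit.locus_tag} ({family})"
                )
            header = f"{genome}|{hit.locus_tag}|{family}"
            records.append((header, seqs[hit.locus_tag]))
            mapping.append((header, family))
    return records, mapping


# ---------------------------------------------------------------------------
# TSV export


def write_calls(calls: Mapping[str, PathwayCall], path: str | Path) -> None:
    families = sorted({f for c in calls.values() for f in c.best_hits})
    cols = ["genome_id", "satisfied"]
    for fam in families:
        cols += [f"{fam}_locus", f"{fam}_evalue"]
    cols.append("missing_families")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for genome in sorted(calls):
            c = calls[genome]
            row = [genome, str(c.satisfied)]
            for fam in families:
                hit = c.best_hits.get(fam)
                row += [hit.locus_tag, f"{hit.e_value:.6g}"] if hit else [".", "."]
            row.append(",".join(sorted(c.missing_families)) or ".")
            fh.write("\t".join(row) + "\n")


def write_prevalence(rows: Sequence[PrevalenceRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tn_genomes\tn_with_pathway\n")
        for r in rows:
            fh.write(f"{r.species_id}\t{r.n_genomes}\t{r.n_with_pathway}\n")
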
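"""Reading and writing organism metabolic data.

Supports the KEGG reaction flat-file dialect (``ENTRY``/``EQUATION`` fields,
entries terminated by ``///``), tab-delimited KO annotation profiles in the
IMG export style, and retrieval of per-organism reaction sets through the
KEGG REST interface with an on-disk cache.

Only reaction *topology* is retained: stoichiometric coefficients are
stripped, and compound identifiers are treated as opaque strings
(canonicalised by uppercasing and whitespace trimming).
"""

from __future__ import annotations

import csv
import re
import urllib.error
import urllib.request
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from .errors import ConnectivityError, FormatError, LookupError_, ParseError

KEGG_REST_BASE = "https://rest.kegg.jp"

# leading stoichiometric coefficient: "2 C00001", "(n+1) C00001", "3n C00002"
_COEF_RE = re.compile(r"^(?:\(.*?\)|[0-9]+n?|n(?:[+-][0-9]+)?)\s+")


def canonicalize_compound(identifier: str) -> str:
    """Uppercase and strip an opaque compound identifier."""
    return identifier.strip().upper()


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: substrate and product compound sets plus reversibility.

    Stoichiometry is deliberately absent — the downstream network is purely
    topological (an edge substrate→product per compound pair).
    """

    reaction_id: str
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool

    def __post_init__(self) -> None:
        if not self.reaction_id:
            raise ValueError("reaction_id must be non-empty")
        if not self.substrates or not self.products:
            raise ValueError(
                f"{self.reaction_id}: substrates and products must be non-empty"
            )
        if any(not c for c in self.substrates | self.products):
            raise ValueError(f"{self.reaction_id}: empty compound identifier")

    @property
    def shared_compounds(self) -> frozenset[str]:
        """Compounds appearing on both sides (flagged by the parser)."""
        return self.substrates & self.products


@dataclass(frozen=True)
class AnnotationProfile:
    """An organism's functional annotation: its set of KO terms."""

    organism_id: str
    ko_terms: frozenset[str]
    gene_count: int = 0


def _split_side(side: str, entry: str, lineno: int) -> frozenset[str]:
    compounds = []
    # terms are separated by " + "; a bare "+" may occur inside a
    # parenthesised coefficient such as "(n+1)"
    for token in re.split(r"(?:^|\s)\+(?:\s|$)", side):
        token = token.strip()
        if not token:
            raise ParseError(f"entry {entry}, line {lineno}: empty term in equation")
        token = _COEF_RE.sub("", token)
        compounds.append(canonicalize_compound(token))
    return frozenset(compounds)


def parse_equation(
    equation: str, entry: str, lineno: int, default_reversible: bool = True
) -> tuple[frozenset[str], frozenset[str], bool]:
    """Split a KEGG-style equation into (substrates, products, reversible).

    ``<=>`` marks a reversible reaction; ``=>`` and ``->`` irreversible.
    A bare ``=`` carries no direction flag and falls back to
    ``default_reversible`` (reversible by default, the conservative
    reading common for KGML-style sources).
    """
    for arrow, reversible in (
        ("<=>", True),
        ("=>", False),
        ("->", False),
        (" = ", default_reversible),
    ):
        if arrow in equation:
            left, _, right = equation.partition(arrow)
            return (
                _split_side(left, entry, lineno),
                _split_side(right, entry, lineno),
                reversible,
            )
    raise ParseError(f"entry {entry}, line {lineno}: no reaction arrow in equation")


def parse_reaction_flatfile(
    stream: TextIO, default_reversible: bool = True
) -> list[ReactionRecord]:
    """Parse KEGG-style reaction entries from a text stream.

    Each entry carries an ``ENTRY`` field naming the reaction and an
    ``EQUATION`` field (continuation lines are indented); entries end with
    ``///``.  Records whose substrate and product sets overlap after
    canonicalisation are kept but flagged with a warning — self-pairs are
    dropped later, at edge construction.  ``default_reversible`` applies
    to equations written with a directionless ``=``.
    """
    records: list[ReactionRecord] = []
    entry_id: str | None = None
    equation_parts: list[str] = []
    entry_line = 0
    in_equation = False
    flagged: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal entry_id, equation_parts, in_equation
        if entry_id is None and not equation_parts:
            return
        if entry_id is None:
            raise ParseError(f"line {lineno}: entry without an ENTRY field")
        if not equation_parts:
            raise ParseError(
                f"entry {entry_id}, line {entry_line}: missing EQUATION field"
            )
        subs, prods, rev = parse_equation(
            " ".join(equation_parts), entry_id, entry_line, default_reversible
        )
        record = ReactionRecord(entry_id, subs, prods, rev)
        if record.shared_compounds:
            flagged.append(entry_id)
        records.append(record)
        entry_id, equation_parts, in_equation = None, [], False

    lineno = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("///"):
            flush(lineno)
            continue
        if line[0] != " ":  # new field
            name, _, value = line.partition(" ")
            in_equation = False
            if name == "ENTRY":
                if entry_id is not None or equation_parts:
                    flush(lineno)
                tokens = value.split()
                if not tokens:
                    raise ParseError(f"line {lineno}: ENTRY field without identifier")
                entry_id = tokens[0]
                entry_line = lineno
            elif name == "EQUATION":
                if not value.strip():
                    raise ParseError(
                        f"entry {entry_id}, line {lineno}: empty EQUATION field"
                    )
                equation_parts.append(value.strip())
                in_equation = True
        elif in_equation:  # indented continuation of EQUATION
            equation_parts.append(line.strip())
    flush(lineno)

    if flagged:
        warnings.warn(
            "reactions with a compound on both sides (self-pairs will be "
            f"dropped): {', '.join(flagged)}",
            stacklevel=2,
        )
    return records


def write_reaction_flatfile(records: Iterable[ReactionRecord], stream: TextIO) -> None:
    """Write records in the same flat dialect :func:`parse_reaction_flatfile` reads."""
    for rec in records:
        arrow = "<=>" if rec.reversible else "=>"
        left = " + ".join(sorted(rec.substrates))
        right = " + ".join(sorted(rec.products))
        stream.write(f"ENTRY       {rec.reaction_id}\n")
        stream.write(f"EQUATION    {left} {arrow} {right}\n")
        stream.write("///\n")


def parse_annotation_profile(stream: TextIO, organism_id: str = "") -> AnnotationProfile:
    """Parse a tab-delimited annotation table with a KO-identifier column.

    The KO column is located by header name (``ko_id``, ``ko`` or
    ``ko_term``, case-insensitive); duplicate terms collapse to a set.
    ``gene_count`` is the number of data rows.
    """
    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError("annotation profile is empty (no header row)") from None
    lowered = [h.strip().lower() for h in header]
    ko_col = next(
        (i for i, h in enumerate(lowered) if h in ("ko_id", "ko", "ko_term")), None
    )
    if ko_col is None:
        raise FormatError(
            f"annotation profile has no KO column (header: {header!r})"
        )
    ko_terms: set[str] = set()
    n_rows = 0
    for row in reader:
        if not any(cell.strip() for cell in row):
            continue
        n_rows += 1
        if ko_col < len(row):
            term = row[ko_col].strip()
            if term:
                ko_terms.add(canonicalize_compound(term.removeprefix("KO:")))
    return AnnotationProfile(organism_id, frozenset(ko_terms), n_rows)


def load_ko_reaction_map(stream: TextIO) -> dict[str, frozenset[str]]:
    """Load a tab-delimited KO→reaction mapping (columns: ko_id, reaction_id)."""
    mapping: dict[str, set[str]] = {}
    for lineno, row in enumerate(csv.reader(stream, delimiter="\t"), start=1):
        if not row or not any(cell.strip() for cell in row):
            continue
        if len(row) < 2:
            raise FormatError(f"KO/reaction map line {lineno}: expected two columns")
        ko, rid = row[0].strip().upper(), row[1].strip()
        if lineno == 1 and ko in ("KO_ID", "KO"):
            continue
        mapping.setdefault(ko, set()).add(rid)
    return {ko: frozenset(rids) for ko, rids in mapping.items()}


def reactions_for_profile(
    profile: AnnotationProfile,
    ko_map: dict[str, frozenset[str]],
    reaction_db: dict[str, ReactionRecord],
) -> list[ReactionRecord]:
    """Resolve an annotation profile to reaction records via a KO→reaction map."""
    if not profile.ko_terms:
        raise FormatError(f"organism {profile.organism_id!r} has no KO terms")
    reaction_ids: set[str] = set()
    for ko in profile.ko_terms:
        reaction_ids |= ko_map.get(ko, frozenset())
    return [reaction_db[rid] for rid in sorted(reaction_ids) if rid in reaction_db]


def _http_get(url: str, timeout: float) -> str:
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            return resp.read().decode()
    except urllib.error.HTTPError as exc:
        if exc.code in (400, 404):
            raise LookupError_(f"KEGG lookup failed for {url}: HTTP {exc.code}") from exc
        raise ConnectivityError(f"KEGG request failed for {url}: {exc}") from exc
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise ConnectivityError(f"cannot reach KEGG at {url}: {exc}") from exc


def fetch_org_metabolic_data(
    org_code: str,
    cache_dir: str | Path,
    *,
    base_url: str = KEGG_REST_BASE,
    timeout: float = 30.0,
    chunk_size: int = 10,
) -> list[ReactionRecord]:
    """Fetch an organism's reaction set from KEGG, caching on disk.

    The cache file ``cache_dir/<org_code>/reactions.txt`` is written in the
    same flat dialect :func:`parse_reaction_flatfile` reads, so a warm cache
    makes repeated calls fully offline and byte-reproducible.
    """
    if not org_code or not org_code.strip():
        raise LookupError_("empty KEGG organism code")
    org_code = org_code.strip()
    cache_file = Path(cache_dir) / org_code / "reactions.txt"
    if cache_file.exists():
        with open(cache_file) as fh:
            return parse_reaction_flatfile(fh)

    link_text = _http_get(f"{base_url}/link/reaction/{org_code}", timeout)
    reaction_ids = sorted(
        {
            line.split("\t")[1].removeprefix("rn:")
            for line in link_text.splitlines()
            if "\t" in line
        }
    )
    if not reaction_ids:
        raise LookupError_(f"no reactions linked to organism code {org_code!r}")
    chunks = [
        reaction_ids[i : i + chunk_size]
        for i in range(0, len(reaction_ids), chunk_size)
    ]
    flat = "".join(_http_get(f"{base_url}/get/{'+'.join(c)}", timeout) for c in chunks)
    records = parse_reaction_flatfile(iter(flat.splitlines(keepends=True)))
    cache_file.parent.mkdir(parents=True, exist_ok=True)
    with open(cache_file, "w") as fh:
        write_reaction_flatfile(records, fh)
    return records
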
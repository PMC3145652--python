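"""Dictionary-filtered gene-mention mining over a sectioned text corpus.

Automated gene-symbol searches over free text drown in false positives
because many official symbols and aliases are ordinary English words (REST,
CAST, GAST ...).  The screen here follows a two-stage design: search terms
are first filtered against an English word list — a symbol that is an
English word is searched case-sensitively in all-capitals form only, while
gene names and past symbols that are English words are dropped outright; all
remaining terms are searched case-insensitively.  Matches are whole-token
only, and matches inside methods or supplementary sections are ignored so
that only genes an author discussed in the narrative (title, abstract, body,
figure captions) count as mentions.  A gene mentioned in at least three
studies crosses the reporting threshold.

The final manual-confirmation pass of such a screen is out of automated
reach; instead a snippet review report (matched token with context) is
emitted for a human reader.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expression_io import COMPARISON_COHORT_TAGS, KNOWN_STUDY_TAGS

SECTION_TAGS = ("title", "abstract", "body", "methods", "supplementary",
                "figure_caption")
EXCLUDED_SECTIONS = frozenset({"methods", "supplementary"})

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


@dataclass(frozen=True)
class LexiconEntry:
    symbol: str
    name: str = ""
    aliases: tuple[str, ...] = ()


@dataclass
class GeneLexicon:
    """Official symbols with names and past symbols, uppercase-normalized."""

    entries: dict[str, LexiconEntry]

    def __post_init__(self) -> None:
        if len({e.symbol for e in self.entries.values()}) != len(self.entries):
            raise ValueError("duplicate symbols in lexicon")


def _ascii_upper(text: str) -> str:
    # ASCII-only case folding; Greek and other non-ASCII pass through verbatim
    return text.translate(str.maketrans(
        "abcdefghijklmnopqrstuvwxyz", "ABCDEFGHIJKLMNOPQRSTUVWXYZ"))


def load_lexicon(path) -> GeneLexicon:
    """Lexicon TSV: columns symbol, name, aliases (pipe-separated)."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = {}
    for _, rec in raw.iterrows():
        symbol = _ascii_upper(rec["symbol"].strip())
        aliases = tuple(_ascii_upper(a.strip())
                        for a in rec.get("aliases", "").split("|") if a.strip())
        entries[symbol] = LexiconEntry(symbol=symbol,
                                       name=rec.get("name", "").strip(),
                                       aliases=aliases)
    return GeneLexicon(entries=entries)


def load_word_list(path) -> frozenset:
    """Plain-text word list, one word per line; '#' lines are comments."""
    words = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            word = line.strip()
            if word and not word.startswith("#"):
                words.add(word.lower())
    return frozenset(words)


@dataclass(frozen=True)
class SearchTerm:
    text: str
    case_sensitive: bool


@dataclass
class SearchPlan:
    symbol: str
    terms: tuple[SearchTerm, ...]
    dropped: tuple[str, ...] = ()

    @property
    def searchable(self) -> bool:
        return bool(self.terms)


def build_search_terms(lexicon: GeneLexicon,
                       words: frozenset) -> dict[str, SearchPlan]:
    """Turn a lexicon into per-gene search plans under the dictionary rules.

    Official symbol in the word list -> one case-sensitive all-capitals term.
    Symbol not in the list -> case-insensitive term.  Names and aliases in
    the word list are dropped; the rest become case-insensitive terms.
    """
    plans = {}
    for symbol, entry in lexicon.entries.items():
        terms: list[SearchTerm] = []
        dropped: list[str] = []
        if symbol.lower() in words:
            terms.append(SearchTerm(_ascii_upper(symbol), case_sensitive=True))
        else:
            terms.append(SearchTerm(symbol, case_sensitive=False))
        for extra in (entry.name, *entry.aliases):
            if not extra:
                continue
            if extra.lower() in words:
                dropped.append(extra)
            else:
                terms.append(SearchTerm(extra, case_sensitive=False))
        plans[symbol] = SearchPlan(symbol=symbol, terms=tuple(terms),
                                   dropped=tuple(dropped))
    return plans


@dataclass(frozen=True)
class Section:
    tag: str
    text: str

    def __post_init__(self) -> None:
        if self.tag not in SECTION_TAGS:
            raise ValueError(f"unknown section tag {self.tag!r}")


@dataclass
class Corpus:
    """Documents keyed by study tag, each an ordered list of tagged sections."""

    documents: dict[str, list[Section]]

    @property
    def studies(self) -> tuple[str, ...]:
        return tuple(self.documents)


def load_corpus_json(path) -> Corpus:
    """JSON corpus: {study: [{"section": tag, "text": ...}, ...], ...}."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    docs = {study: [Section(s["section"], s["text"]) for s in sections]
            for study, sections in data.items()}
    return Corpus(documents=docs)


_HEADER_RE = re.compile(r"^==\s*(\w+)\s*==\s*$")


def load_corpus_dir(directory) -> Corpus:
    """One UTF-8 ``.txt`` file per study; ``== tag ==`` lines open sections.

    Text before the first header belongs to an implicit ``body`` section.
    """
    docs = {}
    for path in sorted(Path(directory).glob("*.txt")):
        sections: list[Section] = []
        tag, buf = "body", []
        for line in path.read_text(encoding="utf-8").splitlines():
            m = _HEADER_RE.match(line)
            if m:
                if "".join(buf).strip():
                    sections.append(Section(tag, "\n".join(buf)))
                tag, buf = m.group(1).lower(), []
            else:
                buf.append(line)
        if "".join(buf).strip():
            sections.append(Section(tag, "\n".join(buf)))
        docs[path.stem] = sections
    return Corpus(documents=docs)


@dataclass
class LiteratureHitTable:
    """Gene x study mention matrix with per-gene counts and verdicts."""

    matrix: pd.DataFrame         # bool, genes x studies
    min_studies: int
    snippets: list[dict] = field(default_factory=list)

    @property
    def counts(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    @property
    def verdicts(self) -> pd.Series:
        return self.counts >= self.min_studies

    def review_report(self) -> pd.DataFrame:
        """Matched snippets with context, for the manual-confirmation pass."""
        return pd.DataFrame(self.snippets,
                            columns=["gene", "study", "section", "term", "context"])


def _match_in_text(term: SearchTerm, text: str) -> int | None:
    """Offset of the first whole-token match of ``term`` in ``text``.

    Multi-word terms (gene names) match as a consecutive token sequence;
    tokens split on any non-alphanumeric character, so hyphenated variants
    like ``TFF-1`` do not match the symbol ``TFF1``.
    """
    want = _TOKEN_RE.findall(term.text)
    if not want:
        return None
    matches = list(_TOKEN_RE.finditer(text))
    if not term.case_sensitive:
        want = [_ascii_upper(w) for w in want]
    for i in range(len(matches) - len(want) + 1):
        window = [m.group(0) for m in matches[i:i + len(want)]]
        if not term.case_sensitive:
            window = [_ascii_upper(w) for w in window]
        if window == want:
            return matches[i].start()
    return None


def scan_corpus(corpus: Corpus, plans: Mapping[str, SearchPlan],
                min_studies: int = 3, context: int = 40) -> LiteratureHitTable:
    """Scan every document for every plan; methods/supplementary excluded."""
    studies = list(corpus.documents)
    genes = list(plans)
    hits = pd.DataFrame(False, index=genes, columns=studies)
    snippets = []
    for study, sections in corpus.documents.items():
        for section in sections:
            if section.tag in EXCLUDED_SECTIONS:
                continue
            for gene, plan in plans.items():
                if hits.at[gene, study]:
                    continue
                for term in plan.terms:
                    pos = _match_in_text(term, section.text)
                    if pos is not None:
                        hits.at[gene, study] = True
                        lo = max(0, pos - context)
                        snippets.append({
                            "gene": gene, "study": study,
                            "section": section.tag, "term": term.text,
                            "context": section.text[lo:pos + len(term.text) + context],
                        })
                        break
    return LiteratureHitTable(matrix=hits, min_studies=min_studies,
                              snippets=snippets)


def independent_ref_count(refs_by_gene: Mapping[str, Iterable[str]],
                          excluded: frozenset = COMPARISON_COHORT_TAGS
                          ) -> pd.Series:
    """Per-gene count of cited studies outside the exclusion set.

    ``refs_by_gene`` maps a gene key to its study tags (duplicates collapse);
    unknown tags are an error so typos cannot silently deflate counts.
    """
    counts = {}
    for gene, tags in refs_by_gene.items():
        tags = set(tags)
        unknown = tags - KNOWN_STUDY_TAGS
        if unknown:
            raise ValueError(f"unknown study tag(s) for {gene}: {sorted(unknown)}")
        counts[gene] = len(tags - excluded)
    return pd.Series(counts, name="independent_refs").sort_index()


def peak_gene_independent_refs(rows) -> pd.Series:
    """Union each unique peak-table gene's reference tags, then count.

    The peak tables' reference columns already exclude the three comparison
    cohorts; genes appearing in both comparisons contribute the union of
    their rows' tags.
    """
    merged: dict[str, set] = {}
    for row in rows:
        merged.setdefault(row.symbol, set()).update(row.refs)
    return independent_ref_count(merged)
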
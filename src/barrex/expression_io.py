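"""Readers, writers and bundled reference tables.

All tabular artifacts are plain TSV (tab-separated, UTF-8, header row, first
column an identifier, no quoting).  Expression matrices are probes x samples;
sample metadata maps sample ids to tissue labels; annotation maps probe ids to
Entrez gene ids and symbols.

The package bundles transcriptions of the printed peak-gene tables from the
four-cohort esophageal profiling comparison (squamous vs Barrett's esophagus
vs adenocarcinoma) together with the table of genes reported across sixteen
profiling studies.  Two distinct kinds of empty cell occur in the peak tables
and are preserved as distinct states: a gene absent from a cohort's platform
(printed as an em dash) versus a gene present but not significant in that
cohort (printed blank).
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical tissue label vocabulary.  "T" (tumor) is accepted on input as an
#: alias for EAC, mirroring dendrogram figure labeling conventions.
TISSUES = ("S", "BE", "EAC")
_LABEL_ALIASES = {"T": "EAC"}

#: Cohort order used throughout the bundled peak tables.
FIXTURE_COHORTS = ("SDH", "GOMES", "GREENAWALT", "HAO")

#: Per-cohort adjusted-p thresholds used for the printed significance counts.
#: The smallest cohort required the relaxed 0.05 threshold to yield any genes.
FIXTURE_THRESHOLDS = {"SDH": 0.01, "GOMES": 0.01, "GREENAWALT": 0.01, "HAO": 0.05}

#: Study tags of the three public comparison cohorts (excluded when counting
#: independent literature support).
COMPARISON_COHORT_TAGS = frozenset({"Gomes", "Hao", "Greenawalt"})

#: All study tags that may appear in reference columns.
KNOWN_STUDY_TAGS = frozenset(
    {
        "Helm", "Kimchi", "Wang", "ElSerag", "Fox", "Ostrowski", "Barrett",
        "Selaru", "Chang", "vanBaal1", "vanBaal2", "Stairs", "Razvi",
        "Gomes", "Hao", "Greenawalt",
    }
)


class Cell(enum.Enum):
    """State of a per-cohort table cell that carries no numeric value."""

    ABSENT = "absent"        # gene not on that cohort's platform ("—")
    NONSIGNIFICANT = "nonsig"  # present but failed the significance filter (blank)


ABSENT = Cell.ABSENT
NONSIGNIFICANT = Cell.NONSIGNIFICANT


class LoadError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# Cohort expression container
# ---------------------------------------------------------------------------

@dataclass
class CohortExpression:
    """One cohort's expression matrix with labels and probe annotation.

    Parameters
    ----------
    name:
        Cohort identifier.
    matrix:
        probes x samples nonnegative reals, probe ids on the index.
    labels:
        Tissue label per sample (``S``, ``BE`` or ``EAC``), indexed by sample.
    annotation:
        Per-probe frame with columns ``entrez`` (nullable integer), ``symbol``
        and ``status`` (``ok`` / ``unmapped`` / ``multimapped``).
    scale:
        ``"linear"`` or ``"log2"``.
    provenance:
        Ordered log of transformations applied so far.
    """

    name: str
    matrix: pd.DataFrame
    labels: pd.Series
    annotation: pd.DataFrame
    scale: str = "linear"
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        # canonical index names so write/read round-trips compare equal
        self.matrix.index.name = "probe_id"
        self.labels.index.name = "sample_id"
        self.annotation.index.name = "probe_id"
        self.validate()

    def validate(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise LoadError(f"unknown scale flag {self.scale!r}")
        if self.matrix.shape[0] < 1:
            raise LoadError("expression matrix has no probes")
        if not self.matrix.index.is_unique:
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise LoadError(f"duplicate probe ids: {list(dupes[:5])}")
        missing = [s for s in self.matrix.columns if s not in self.labels.index]
        if missing:
            raise LoadError(f"samples missing from metadata: {missing}")
        bad = sorted(set(self.labels.unique()) - set(TISSUES))
        if bad:
            raise LoadError(f"unknown tissue labels: {bad}")
        extra = [p for p in self.matrix.index if p not in self.annotation.index]
        if extra:
            raise LoadError(f"probes missing from annotation: {extra[:5]}")

    @property
    def samples(self) -> pd.Index:
        return self.matrix.columns

    def group_samples(self) -> dict[str, list[str]]:
        """Sample ids per tissue group, in canonical tissue order."""
        lab = self.labels.loc[self.matrix.columns]
        return {t: list(lab.index[lab == t]) for t in TISSUES if (lab == t).any()}

    def require_three_groups(self, min_per_group: int = 2) -> None:
        groups = self.group_samples()
        small = [t for t, s in groups.items() if len(s) < min_per_group]
        if len(groups) < 3 or small:
            raise LoadError(
                f"cohort {self.name}: need 3 tissue groups with >= "
                f"{min_per_group} samples each, got "
                f"{ {t: len(s) for t, s in groups.items()} }"
            )

    def copy_with(self, **kwargs) -> "CohortExpression":
        return replace(self, **kwargs)


def _normalize_labels(raw: pd.Series) -> pd.Series:
    lab = raw.astype(str).str.strip()
    return lab.replace(_LABEL_ALIASES)


def read_cohort(expr_path, meta_path, annot_path, name: str | None = None,
                scale: str = "linear") -> CohortExpression:
    """Load and validate one cohort from its three TSV files.

    The annotation file has columns ``probe_id``, ``entrez_id``, ``symbol``.
    A probe listed on several rows with different Entrez ids is retained but
    flagged ``multimapped``; an empty/NA Entrez id flags it ``unmapped``.
    Flagged probes stay in the matrix and are excluded later, at the
    probe-to-gene mapping stage.
    """
    expr_path, meta_path, annot_path = Path(expr_path), Path(meta_path), Path(annot_path)
    matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique()
        raise LoadError(f"{expr_path.name}: duplicate probe id(s) {list(dupes[:5])}")

    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    if "tissue" not in meta.columns:
        raise LoadError(f"{meta_path.name}: missing 'tissue' column")
    meta.index = meta.index.astype(str)
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise LoadError(f"{meta_path.name}: samples missing from metadata: {missing}")
    labels = _normalize_labels(meta["tissue"]).loc[list(matrix.columns)]

    annotation = read_annotation(annot_path)
    return CohortExpression(
        name=name or expr_path.stem,
        matrix=matrix,
        labels=labels,
        annotation=annotation,
        scale=scale,
    )


def read_annotation(path) -> pd.DataFrame:
    """Read a probe annotation TSV into the canonical per-probe frame."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = {"probe_id", "entrez_id", "symbol"}
    if not expected.issubset(raw.columns):
        raise LoadError(f"{Path(path).name}: expected columns {sorted(expected)}")
    return build_annotation(
        raw["probe_id"], raw["entrez_id"].replace("", None), raw["symbol"]
    )


def build_annotation(probe_ids: Iterable, entrez_ids: Iterable,
                     symbols: Iterable) -> pd.DataFrame:
    """Collapse possibly repeated probe rows into one flagged row per probe."""
    df = pd.DataFrame({
        "probe_id": [str(p) for p in probe_ids],
        "entrez": list(entrez_ids),
        "symbol": [str(s).upper() if s is not None and str(s) != "" else "" for s in symbols],
    })
    records = {}
    for probe, grp in df.groupby("probe_id", sort=False):
        ids = {int(e) for e in grp["entrez"] if e is not None and not pd.isna(e)}
        symbol = next((s for s in grp["symbol"] if s), "")
        if len(ids) == 0:
            records[probe] = (pd.NA, symbol, "unmapped")
        elif len(ids) > 1:
            records[probe] = (pd.NA, symbol, "multimapped")
        else:
            records[probe] = (ids.pop(), symbol, "ok")
    out = pd.DataFrame.from_dict(records, orient="index",
                                 columns=["entrez", "symbol", "status"])
    out.index.name = "probe_id"
    out["entrez"] = out["entrez"].astype("Int64")
    return out


def write_cohort(cohort: CohortExpression, out_dir) -> dict[str, Path]:
    """Write a cohort's three TSV files; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": out_dir / f"{cohort.name}_expression.tsv",
        "meta": out_dir / f"{cohort.name}_samples.tsv",
        "annot": out_dir / f"{cohort.name}_annotation.tsv",
    }
    cohort.matrix.to_csv(paths["expr"], sep="\t", index_label="probe_id")
    cohort.labels.rename("tissue").to_frame().to_csv(
        paths["meta"], sep="\t", index_label="sample_id")
    rows = []
    for probe, rec in cohort.annotation.iterrows():
        entrez = "" if pd.isna(rec["entrez"]) else str(int(rec["entrez"]))
        if rec["status"] == "multimapped":
            # emit two conflicting rows so the flag round-trips through TSV
            rows.append((probe, "1", rec["symbol"]))
            rows.append((probe, "2", rec["symbol"]))
        else:
            rows.append((probe, entrez, rec["symbol"]))
    pd.DataFrame(rows, columns=["probe_id", "entrez_id", "symbol"]).to_csv(
        paths["annot"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Bundled fixture tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakGeneRow:
    """One row of a printed peak-gene table."""

    entrez: int
    symbol: str
    direction: str                       # "up" or "down"
    p_values: Mapping[str, float | Cell]  # per cohort
    pass_count_printed: tuple[int, int]
    folds: Mapping[str, float | Cell]    # signed display folds per cohort
    refs: tuple[str, ...]                # independent profiling study tags
    source_table: str                    # "T1", "T2" or "T3"

    @property
    def comparison(self) -> str:
        return "S_BE" if self.source_table in ("T1", "T2") else "BE_EAC"

    def present_cohorts(self) -> tuple[str, ...]:
        return tuple(c for c in FIXTURE_COHORTS if self.p_values[c] is not ABSENT)


def _parse_cell(text: str) -> float | Cell:
    text = text.strip()
    if text == "-":
        return ABSENT
    if text == "":
        return NONSIGNIFICANT
    return float(text)


def _fixture_path(name: str):
    return resources.files("barrex.data").joinpath(name)


def _load_peak_table(name: str, tag: str) -> list[PeakGeneRow]:
    rows = []
    with _fixture_path(name).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            parts += [""] * (ncol - len(parts))
            rec = dict(zip(header, parts))
            num, den = rec["count_printed"].split("/")
            p_values = {c: _parse_cell(rec[f"p_{c.lower()}"]) for c in FIXTURE_COHORTS}
            folds = {c: _parse_cell(rec[f"fold_{c.lower()}"]) for c in FIXTURE_COHORTS}
            refs = tuple(t for t in rec["refs"].split(",") if t)
            unknown = set(refs) - KNOWN_STUDY_TAGS
            if unknown:
                raise LoadError(f"{name}: unknown study tag(s) {sorted(unknown)}")
            rows.append(PeakGeneRow(
                entrez=int(rec["entrez"]),
                symbol=rec["symbol"].upper(),
                direction=rec["direction"],
                p_values=p_values,
                pass_count_printed=(int(num), int(den)),
                folds=folds,
                refs=refs,
                source_table=tag,
            ))
    return rows


def load_fixture_tables() -> list[PeakGeneRow]:
    """All bundled peak-gene rows: squamous-vs-BE (down, up) then BE-vs-EAC."""
    return (
        _load_peak_table("peak_s_be_down.tsv", "T1")
        + _load_peak_table("peak_s_be_up.tsv", "T2")
        + _load_peak_table("peak_be_eac.tsv", "T3")
    )


@dataclass(frozen=True)
class LiteratureReportRow:
    """One row of the cross-study literature report table."""

    hgnc_id: int
    symbol: str
    description: str
    aliases: tuple[str, ...]
    ref_count_printed: int
    study_tags: tuple[str, ...]

    @property
    def independent_tags(self) -> tuple[str, ...]:
        return tuple(t for t in self.study_tags if t not in COMPARISON_COHORT_TAGS)


def load_table4_fixture() -> list[LiteratureReportRow]:
    """Genes reported in >= 3 of the 16 esophageal profiling studies."""
    rows = []
    with _fixture_path("literature_reports.tsv").open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            parts += [""] * (ncol - len(parts))
            rec = dict(zip(header, parts))
            tags = tuple(t for t in rec["refs"].split(",") if t)
            unknown = set(tags) - KNOWN_STUDY_TAGS
            if unknown:
                raise LoadError(f"literature_reports: unknown tags {sorted(unknown)}")
            aliases = tuple(a for a in (rec["alias1"], rec["alias2"]) if a)
            rows.append(LiteratureReportRow(
                hgnc_id=int(rec["hgnc_id"]),
                symbol=rec["symbol"].upper(),
                description=rec["description"],
                aliases=aliases,
                ref_count_printed=int(rec["ref_count"]),
                study_tags=tags,
            ))
    return rows


def bundled_word_list_path():
    """Path-like handle on the small demonstration English word list."""
    return _fixture_path("english_words_demo.txt")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets over a declared universe of gene identifiers."""

    sets: dict[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise LoadError(f"gene set {name!r} is empty")
            stray = members - self.universe
            if stray:
                raise LoadError(
                    f"gene set {name!r} has members outside the universe: "
                    f"{sorted(stray)[:5]}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, universe: Iterable | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members per line).

    If no universe is supplied it is inferred as the union of all members.
    Duplicate members within a set are deduplicated with a logged warning.
    """
    sets: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise LoadError(f"{Path(path).name}:{lineno}: malformed GMT line "
                                "(need name, description, >=1 member)")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise LoadError(f"{Path(path).name}:{lineno}: set {name!r} has no members")
            if len(members) != len(set(members)):
                logger.warning("GMT set %s: duplicate members deduplicated", name)
            sets[name] = frozenset(members)
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    else:
        universe = frozenset(universe)
    return GeneSetCollection(sets=sets, universe=universe)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default),
                          encoding="utf-8")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
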
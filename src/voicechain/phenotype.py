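"""Speech-effect categorization and syndrome-cohort statistics.

Reported speech effects of microdeletion syndromes are mapped onto a closed
taxonomy — absent, apraxic, delayed, dysarthric, idiosyncratic, impaired,
or normal speech — using the abbreviation codes conventional in the source
tables (Del, Imp, Norm, Abs, Apr, Dys, Idio) plus a small phrase map for
rows written out in words. The cohort builder merges duplicate-region rows
(regions split in the clinical literature by symptoms rather than gene
content), drops rows with no speech information, and the statistics
functions summarize level-2 chainlink counts and connectivities per
category.

Conventions that matter downstream:

* Idiosyncratic speech is an apraxia-adjacent presentation and is folded
  into APRAXIC for aggregation by default.
* A syndrome contributes to *every* non-normal category its effects list.
  NORMAL is, by default, the group of syndromes whose reported speech is
  exclusively normal (``normal_exclusive=True``) — a syndrome reported as
  "Norm or Del" is delayed-speech evidence, not normal-speech evidence.
  Set ``normal_exclusive=False`` to let such rows count toward NORMAL too.
* Category statistics use the level-2 chainlink count and connectivity:
  level-1 chainlink sets hold one or two genes and are too small to model.
"""
from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from statistics import mean, median

__all__ = [
    "SpeechCategory",
    "SyndromeRecord",
    "Cohort",
    "CategoryStats",
    "CooccurrenceSummary",
    "parse_effects",
    "build_cohort",
    "cooccurrence_stats",
    "category_stats",
    "SEVERITY_ORDER",
]


class SpeechCategory(enum.Enum):
    NORMAL = "normal"
    APRAXIC = "apraxic"
    DYSARTHRIC = "dysarthric"
    IMPAIRED = "impaired"
    DELAYED = "delayed"
    ABSENT = "absent"
    IDIOSYNCRATIC = "idiosyncratic"


#: Reporting order, least to most severe (idiosyncratic folds into apraxic).
SEVERITY_ORDER = [
    SpeechCategory.NORMAL,
    SpeechCategory.APRAXIC,
    SpeechCategory.DYSARTHRIC,
    SpeechCategory.IMPAIRED,
    SpeechCategory.DELAYED,
    SpeechCategory.ABSENT,
]

_CODE_TOKENS = {
    "del": SpeechCategory.DELAYED,
    "imp": SpeechCategory.IMPAIRED,
    "norm": SpeechCategory.NORMAL,
    "abs": SpeechCategory.ABSENT,
    "apr": SpeechCategory.APRAXIC,
    "dys": SpeechCategory.DYSARTHRIC,
    "idio": SpeechCategory.IDIOSYNCRATIC,
}

# Word-form synonyms for rows written out instead of coded.
_WORD_TOKENS = {
    "delayed": SpeechCategory.DELAYED,
    "impaired": SpeechCategory.IMPAIRED,
    "normal": SpeechCategory.NORMAL,
    "absent": SpeechCategory.ABSENT,
    "apraxia": SpeechCategory.APRAXIC,
    "apraxic": SpeechCategory.APRAXIC,
    "dysarthria": SpeechCategory.DYSARTHRIC,
    "dysarthric": SpeechCategory.DYSARTHRIC,
    "idiosyncratic": SpeechCategory.IDIOSYNCRATIC,
}

# Rows with no code token but an explicit no-speech-anomaly reading.
_NORMAL_PHRASES = (
    "no significant",
    "sensorineural hearing loss",
)

_UNCATEGORIZABLE = ("not available",)


def parse_effects(text: str) -> frozenset[SpeechCategory]:
    """Map a free-text reported-effects string to speech categories.

    Every word-bounded occurrence of a code token (case-insensitive)
    contributes its category; uncoded texts matching a no-anomaly phrase map
    to ``{NORMAL}``. Texts with no recognizable content yield the empty set,
    which callers treat as "uncategorizable". Deterministic and insensitive
    to token order.
    """
    low = text.lower()
    cats: set[SpeechCategory] = set()
    for tok, cat in {**_CODE_TOKENS, **_WORD_TOKENS}.items():
        if re.search(rf"\b{tok}\b", low):
            cats.add(cat)
    if cats:
        return frozenset(cats)
    if any(p in low for p in _UNCATEGORIZABLE):
        return frozenset()
    if any(p in low for p in _NORMAL_PHRASES):
        return frozenset({SpeechCategory.NORMAL})
    return frozenset()


@dataclass(frozen=True)
class SyndromeRecord:
    """One syndrome row: chain counts, implicated genes, reported effects."""

    name: str
    vn1_count: int
    vn1_connectivity: int
    vn2_count: int
    vn2_connectivity: int
    implicated: frozenset[str] = frozenset()
    effects_text: str = ""
    categories: frozenset[SpeechCategory] = frozenset()
    merged_names: tuple[str, ...] = ()

    @property
    def analyzable(self) -> bool:
        return bool(self.categories)

    @property
    def has_anomaly(self) -> bool:
        return bool(self.categories - {SpeechCategory.NORMAL})

    @staticmethod
    def from_row(name: str, vn1_count: int, vn1_connectivity: int,
                 vn2_count: int, vn2_connectivity: int,
                 implicated: frozenset[str] = frozenset(),
                 effects_text: str = "") -> "SyndromeRecord":
        return SyndromeRecord(
            name=name, vn1_count=vn1_count, vn1_connectivity=vn1_connectivity,
            vn2_count=vn2_count, vn2_connectivity=vn2_connectivity,
            implicated=implicated, effects_text=effects_text,
            categories=parse_effects(effects_text),
        )


_SUBROW = re.compile(r"\s*\((a|b|c)\)$")


def _base_name(name: str) -> str:
    return _SUBROW.sub("", name)


@dataclass(frozen=True)
class Cohort:
    """The analyzable syndrome cohort after merging and exclusion."""

    records: tuple[SyndromeRecord, ...]
    excluded: tuple[SyndromeRecord, ...] = ()

    @property
    def size(self) -> int:
        return len(self.records)


def build_cohort(records: list[SyndromeRecord]) -> Cohort:
    """Merge duplicate-region rows and drop rows without speech information.

    Rows whose names are equal after stripping an ``(a)``/``(b)`` sub-row
    suffix are versions of the same region split by symptoms: they are
    merged into one record carrying the union of categories, implicated
    genes and effects text, and a single copy of the chain counts. Rows with
    identical names but differing counts are an integrity error.
    """
    merged: dict[str, SyndromeRecord] = {}
    order: list[str] = []
    for rec in records:
        base = _base_name(rec.name)
        if base not in merged:
            merged[base] = replace(rec, name=base, merged_names=(rec.name,))
            order.append(base)
            continue
        prev = merged[base]
        counts = (rec.vn1_count, rec.vn1_connectivity,
                  rec.vn2_count, rec.vn2_connectivity)
        if counts != (prev.vn1_count, prev.vn1_connectivity,
                      prev.vn2_count, prev.vn2_connectivity):
            raise ValueError(
                f"ambiguous merge for region {base!r}: duplicate rows carry "
                f"different chain counts"
            )
        merged[base] = replace(
            prev,
            implicated=prev.implicated | rec.implicated,
            effects_text=(prev.effects_text + "; " + rec.effects_text).strip("; "),
            categories=prev.categories | rec.categories,
            merged_names=prev.merged_names + (rec.name,),
        )
    kept = tuple(merged[n] for n in order if merged[n].analyzable)
    dropped = tuple(merged[n] for n in order if not merged[n].analyzable)
    return Cohort(records=kept, excluded=dropped)


@dataclass(frozen=True)
class CooccurrenceSummary:
    n_level1: int
    n_level2_only: int
    pct_level1_with_anomaly: float
    pct_level2_with_anomaly: float


def cooccurrence_stats(cohort: Cohort) -> CooccurrenceSummary:
    """Co-occurrence of voice chains with reported speech anomalies.

    ``pct_level1_with_anomaly`` is computed within the subset of syndromes
    that have level-1 chains; ``pct_level2_with_anomaly`` over the whole
    cohort (every syndrome has level-2 chains in the motivating data; any
    non-NORMAL category counts as an anomaly). Percentages are rounded to
    one decimal.
    """
    if cohort.size == 0:
        raise ValueError("empty cohort")
    lvl1 = [r for r in cohort.records if r.vn1_count > 0]
    n1 = len(lvl1)
    pct1 = round(100.0 * sum(r.has_anomaly for r in lvl1) / n1, 1) if n1 else 0.0
    pct2 = round(100.0 * sum(r.has_anomaly for r in cohort.records) / cohort.size, 1)
    return CooccurrenceSummary(
        n_level1=n1,
        n_level2_only=cohort.size - n1,
        pct_level1_with_anomaly=pct1,
        pct_level2_with_anomaly=pct2,
    )


@dataclass(frozen=True)
class CategoryStats:
    """Per-category summary of level-2 chainlink counts and connectivities."""

    category: SpeechCategory
    count: int
    mean_count: float | None
    median_count: float | None
    mean_connectivity: float | None
    median_connectivity: float | None
    members: tuple[str, ...] = field(default=(), repr=False)


def _group_members(cohort: Cohort, fold_idiosyncratic: bool,
                   normal_exclusive: bool) -> dict[SpeechCategory, list[SyndromeRecord]]:
    groups: dict[SpeechCategory, list[SyndromeRecord]] = {c: [] for c in SEVERITY_ORDER}
    if not fold_idiosyncratic:
        groups[SpeechCategory.IDIOSYNCRATIC] = []
    for rec in cohort.records:
        cats = set(rec.categories)
        if fold_idiosyncratic and SpeechCategory.IDIOSYNCRATIC in cats:
            cats = (cats - {SpeechCategory.IDIOSYNCRATIC}) | {SpeechCategory.APRAXIC}
        for c in cats - {SpeechCategory.NORMAL}:
            groups[c].append(rec)
        if SpeechCategory.NORMAL in cats:
            if not normal_exclusive or cats == {SpeechCategory.NORMAL}:
                groups[SpeechCategory.NORMAL].append(rec)
    return groups


def category_stats(
    cohort: Cohort,
    fold_idiosyncratic: bool = True,
    normal_exclusive: bool = True,
) -> tuple[list[CategoryStats], list[SpeechCategory]]:
    """Per-category statistics and the severity rank ordering.

    Returns the statistics rows in reporting (severity) order together with
    the categories rank-ordered by ascending mean level-2 chainlink count,
    ties broken by ascending mean connectivity. Medians use the midpoint of
    the middle two values for even group sizes. Categories with no members
    are reported with null statistics and sort last.
    """
    groups = _group_members(cohort, fold_idiosyncratic, normal_exclusive)
    stats: list[CategoryStats] = []
    for cat in groups:
        recs = groups[cat]
        if not recs:
            stats.append(CategoryStats(cat, 0, None, None, None, None))
            continue
        cnts = [r.vn2_count for r in recs]
        conns = [r.vn2_connectivity for r in recs]
        stats.append(CategoryStats(
            category=cat, count=len(recs),
            mean_count=mean(cnts), median_count=median(cnts),
            mean_connectivity=mean(conns), median_connectivity=median(conns),
            members=tuple(r.name for r in recs),
        ))
    by_cat = {s.category: s for s in stats}
    ordering = sorted(
        by_cat,
        key=lambda c: (by_cat[c].mean_count is None,
                       by_cat[c].mean_count or 0.0,
                       by_cat[c].mean_connectivity or 0.0),
    )
    ordered_stats = [by_cat[c] for c in groups]
    return ordered_stats, ordering
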
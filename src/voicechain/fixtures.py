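"""Packaged reference fixtures.

Two small plain-text fixtures ship with the package:

* ``acc_pathway.gmt`` — the 63-gene Adenoid Cystic Carcinoma (ACC) pathway,
  the unique FOXP2-containing pathway of the pathway collection used in the
  motivating study.
* ``table1_fixture.tsv`` — the transcription of the study's per-syndrome
  summary table: 76 microdeletion-syndrome rows with implicated genes,
  level-1/level-2 chainlink counts, the parenthesized chainlink
  connectivities, and the reported speech effects. Rows whose counts were
  printed as "same as above" carry the marker ``same`` and inherit the
  preceding row's counts on load.
"""
from __future__ import annotations

import csv
from importlib import resources

from .pathway_io import PathwayEnsemble, normalize_symbol, read_gmt
from .phenotype import SyndromeRecord

__all__ = ["acc_pathway_path", "table1_path", "load_acc_ensemble", "load_table1"]

_COUNT_COLS = ("vn1_count", "vn1_connectivity", "vn2_count", "vn2_connectivity")


def acc_pathway_path():
    """Filesystem path of the packaged ACC pathway GMT file."""
    return resources.files("voicechain.data") / "acc_pathway.gmt"


def table1_path():
    """Filesystem path of the packaged syndrome-table transcription."""
    return resources.files("voicechain.data") / "table1_fixture.tsv"


def load_acc_ensemble() -> PathwayEnsemble:
    """The single-pathway ensemble holding the 63-gene ACC pathway."""
    with resources.as_file(acc_pathway_path()) as p:
        return read_gmt(p)


def load_table1() -> list[SyndromeRecord]:
    """All 76 syndrome rows of the packaged table, in printed order.

    "Same as above" count cells are resolved against the directly preceding
    row, as in the printed table. Merging of duplicate regions and exclusion
    of non-analyzable rows is deliberately left to
    :func:`voicechain.phenotype.build_cohort`.
    """
    records: list[SyndromeRecord] = []
    prev_counts: tuple[int, int, int, int] | None = None
    with resources.as_file(table1_path()) as p, open(p, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["vn2_count"].strip().lower() == "same":
                if prev_counts is None:
                    raise ValueError(f"row {row['syndrome']!r}: 'same' with no prior row")
                counts = prev_counts
            else:
                counts = tuple(int(row[c]) for c in _COUNT_COLS)  # type: ignore[assignment]
            prev_counts = counts
            implicated = frozenset(
                normalize_symbol(t) for t in row["implicated"].split(",") if t.strip()
            )
            records.append(SyndromeRecord.from_row(
                name=row["syndrome"], vn1_count=counts[0], vn1_connectivity=counts[1],
                vn2_count=counts[2], vn2_connectivity=counts[3],
                implicated=implicated, effects_text=row["effects"],
            ))
    return records
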
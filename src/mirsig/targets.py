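"""miRNA→mRNA target-score filtering.

Target-prediction exports (miRanda/mirSVR style) list one predicted binding
site per row with a regression score where more negative means stronger
predicted repression.  The filter retains records with score strictly below a
threshold (−1.25 by default), deduplicates genes per miRNA keeping the most
negative score, and summarizes per-miRNA target-set sizes; gene sets can be
exported in GMT form for any downstream enrichment tool.  Pathway enrichment
itself is out of scope here: it depends on proprietary knowledge bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .exceptions import FormatError, ValidationError

DEFAULT_SCORE_THRESHOLD = -1.25

COLUMNS = ("mirna_id", "target_gene_id", "score")


@dataclass
class TargetScoreRecord:
    """One predicted miRNA→gene interaction with its mirSVR-style score."""

    mirna_id: str
    target_gene_id: str
    score: float


def read_target_scores(path: str | Path, *, sep: str = "\t") -> pd.DataFrame:
    """Parse a (mirna_id, target_gene_id, score) table; a header row naming
    the columns is accepted.  Malformed rows raise :class:`FormatError` with
    their line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split(sep)]
            if lineno == 1 and parts[: len(COLUMNS)] == list(COLUMNS):
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 fields, got {len(parts)}")
            try:
                score = float(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric score {parts[2]!r}"
                ) from None
            rows.append((parts[0], parts[1], score))
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    return df


def filter_target_scores(
    records: pd.DataFrame,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> tuple[pd.DataFrame, pd.Series]:
    """Retain records with score strictly less than ``threshold`` and
    deduplicate genes per miRNA, keeping the most negative score per
    (miRNA, gene) pair.

    Returns ``(filtered, counts)`` where ``counts`` maps miRNA id to its
    number of distinct retained target genes.
    """
    if not pd.notna(threshold) or not abs(threshold) < float("inf"):
        raise ValidationError("threshold must be finite")
    missing = [c for c in COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"records missing column(s): {', '.join(missing)}")
    if not records["score"].map(lambda s: pd.notna(s) and abs(s) < float("inf")).all():
        raise ValidationError("all scores must be finite")
    kept = records[records["score"] < threshold]
    filtered = (
        kept.sort_values(["mirna_id", "target_gene_id", "score"], kind="mergesort")
        .groupby(["mirna_id", "target_gene_id"], as_index=False, sort=True)
        .first()[list(COLUMNS)]
    )
    counts = filtered.groupby("mirna_id")["target_gene_id"].nunique()
    counts.name = "n_targets"
    return filtered.reset_index(drop=True), counts


def write_gmt(filtered: pd.DataFrame, path: str | Path, *, description: str = "mirsig targets") -> Path:
    """Write one GMT gene-set line per miRNA (set name = miRNA id)."""
    path = Path(path)
    with open(path, "w") as fh:
        for mirna, group in filtered.groupby("mirna_id", sort=True):
            genes = sorted(group["target_gene_id"].unique())
            fh.write("\t".join([str(mirna), description] + genes) + "\n")
    return path
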
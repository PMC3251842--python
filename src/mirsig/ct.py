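"""Cycle-threshold (Ct) table processing.

TaqMan low-density-array cards report one Ct value per probe/sample well; a
well whose amplification never crosses the detection threshold is reported as
"Undetermined".  This module parses such tables, imputes undetected wells at
the instrument ceiling (Ct = 40 by default, the maximum cycle), normalizes to
ΔCt against endogenous-control wells, and provides the comparative-Ct
(2^−ΔΔCt) fold change used for single-gene validation.

Conventions
-----------
Ct is on a log2 expression scale and *inversely* related to abundance: one
cycle lower means roughly twice as much transcript.  All matrices are probes
(rows) × samples (columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, StageOrderError, ValidationError

CT_MIN = 0.0
CT_MAX = 40.0

#: Cell tokens (case-insensitive, stripped) that denote an undetected well.
UNDETECTED_TOKENS = frozenset({"undetermined", "undetected", ""})

#: Canonical serialization of an undetected well.
UNDETECTED_LITERAL = "Undetermined"


class ImputedFoldChangeWarning(UserWarning):
    """A ceiling-imputed well entered a fold-change computation; because the
    true Ct exceeds the ceiling, the resulting fold change may be inflated."""


def _check_unique(ids: pd.Index, what: str) -> None:
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate {what} identifier(s): {', '.join(map(str, dup))}")


@dataclass
class CtMatrix:
    """Raw probe × sample Ct readout with per-well detection flags.

    Parameters
    ----------
    values : DataFrame
        Ct cycles; NaN wherever the well is undetected and not yet imputed.
    detected : DataFrame of bool
        True where the instrument reported a numeric Ct.
    control_probe_ids : tuple of str
        Endogenous-control rows (e.g. U6 snRNA) used for ΔCt normalization.
    imputed : DataFrame of bool, optional
        True where an undetected well has been filled at the ceiling.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    control_probe_ids: tuple[str, ...] = ()
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.control_probe_ids = tuple(self.control_probe_ids)
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        if not self.values.index.equals(self.detected.index) or not self.values.columns.equals(
            self.detected.columns
        ):
            raise ValidationError("values and detected must share probe/sample axes")
        missing = [p for p in self.control_probe_ids if p not in self.values.index]
        if missing:
            raise ValidationError(f"control probe(s) not in matrix: {', '.join(missing)}")
        det = self.detected.to_numpy(dtype=bool)
        vals = self.values.to_numpy(dtype=float)
        filled = det if self.imputed is None else det | self.imputed.to_numpy(dtype=bool)
        if np.isnan(vals[filled]).any():
            raise ValidationError("detected/imputed wells must hold numeric Ct values")
        finite = vals[det]
        if finite.size and (np.nanmin(finite) < CT_MIN or np.nanmax(finite) > CT_MAX):
            raise ValidationError(f"detected Ct values must lie in [{CT_MIN}, {CT_MAX}]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def assay_probe_ids(self) -> list[str]:
        """Probe rows that are not endogenous controls."""
        ctrl = set(self.control_probe_ids)
        return [p for p in self.values.index if p not in ctrl]

    @property
    def is_complete(self) -> bool:
        """True when every well holds a numeric value (detected or imputed)."""
        return not self.values.isna().to_numpy().any()

    def n_undetected(self) -> int:
        return int((~self.detected.to_numpy(dtype=bool)).sum())

    def copy(self) -> "CtMatrix":
        return CtMatrix(
            values=self.values.copy(),
            detected=self.detected.copy(),
            control_probe_ids=self.control_probe_ids,
            imputed=None if self.imputed is None else self.imputed.copy(),
        )


@dataclass
class DeltaCtMatrix:
    """Control-normalized expression (ΔCt); the feature space for all
    downstream statistics and classification.

    ``normalization_mode`` records whether each sample was normalized against
    its own control wells (``per_sample``) or against a single scalar control
    mean pooled across all samples (``global``).
    """

    values: pd.DataFrame
    normalization_mode: str
    control_probe_ids: tuple[str, ...] = ()
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.normalization_mode not in ("per_sample", "global"):
            raise ValidationError(
                f"normalization_mode must be 'per_sample' or 'global', got {self.normalization_mode!r}"
            )
        self.control_probe_ids = tuple(self.control_probe_ids)
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def assay_values(self) -> pd.DataFrame:
        """ΔCt values with control rows dropped."""
        return self.values.drop(index=list(self.control_probe_ids), errors="ignore")

    def restrict(self, probes: Sequence[str]) -> pd.DataFrame:
        """ΔCt rows for ``probes``, in that order; missing probes raise."""
        missing = [p for p in probes if p not in self.values.index]
        if missing:
            raise ValidationError(f"probe(s) absent from matrix: {', '.join(missing)}")
        return self.values.loc[list(probes)]


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------

def load_ct_table(
    path: str | Path,
    *,
    sep: str = "\t",
    control_probes: Iterable[str] = (),
) -> CtMatrix:
    """Parse a delimited Ct table (first column probe id, remaining columns
    samples) into a :class:`CtMatrix`.

    ``Undetermined`` / ``undetected`` / empty cells become undetected wells.
    Malformed cells raise :class:`FormatError` naming the offending
    probe/sample coordinates.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, index_col=0)
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    dup = raw.index[raw.index.duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicate probe id(s): {', '.join(dup)}")
    dup = raw.columns[raw.columns.duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicate sample id(s): {', '.join(dup)}")

    cells = raw.apply(lambda col: col.str.strip())
    undetected = cells.apply(lambda col: col.str.lower().isin(UNDETECTED_TOKENS))
    numeric = cells.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~undetected
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {cells.iat[r, c]!r} at probe "
            f"{cells.index[r]!r}, sample {cells.columns[c]!r}"
        )
    out_of_range = (numeric < CT_MIN) | (numeric > CT_MAX)
    if out_of_range.to_numpy(dtype=bool).any():
        r, c = np.argwhere(out_of_range.to_numpy(dtype=bool))[0]
        raise FormatError(
            f"{path}: Ct value {numeric.iat[r, c]} outside [{CT_MIN}, {CT_MAX}] at "
            f"probe {cells.index[r]!r}, sample {cells.columns[c]!r}"
        )
    values = numeric.mask(undetected).astype(float)
    values.index.name = None
    values.columns.name = None
    detected = ~undetected
    detected.index.name = None
    detected.columns.name = None
    controls = tuple(p for p in control_probes if p in values.index)
    return CtMatrix(values=values, detected=detected, control_probe_ids=controls)


def write_ct_table(matrix: CtMatrix, path: str | Path, *, sep: str = "\t") -> Path:
    """Serialize a Ct table; undetected wells are written as the literal
    ``Undetermined`` token regardless of any ceiling imputation."""
    path = Path(path)
    out = matrix.values.copy().astype(object)
    out = out.mask(~matrix.detected, UNDETECTED_LITERAL)
    out.index.name = "probe_id"
    out.to_csv(path, sep=sep)
    return path


# ---------------------------------------------------------------------------
# Imputation and normalization
# ---------------------------------------------------------------------------

def impute_undetected(matrix: CtMatrix, ceiling: float = 40.0) -> CtMatrix:
    """Assign undetected wells the ceiling cycle (Ct = 40 by default, the
    maximum cycle of the run) and mark them imputed.

    Detected wells are untouched and the operation is idempotent.
    """
    det = matrix.detected.to_numpy(dtype=bool)
    observed = matrix.values.to_numpy(dtype=float)[det]
    if observed.size and ceiling < np.nanmax(observed):
        raise ValidationError(
            f"ceiling {ceiling} is below the maximum detected Ct {np.nanmax(observed):.3f}"
        )
    values = matrix.values.mask(~matrix.detected, ceiling)
    imputed = ~matrix.detected
    return CtMatrix(
        values=values,
        detected=matrix.detected.copy(),
        control_probe_ids=matrix.control_probe_ids,
        imputed=imputed,
    )


def normalize_delta_ct(
    matrix: CtMatrix,
    mode: str = "per_sample",
    *,
    drop_controls: bool = False,
) -> DeltaCtMatrix:
    """Normalize Ct to ΔCt by subtracting the endogenous-control mean.

    ``per_sample`` (the standard ΔCt convention, and the default) subtracts
    each sample's own control-well mean, cancelling per-sample loading
    differences; ``global`` subtracts the single scalar mean of all control
    wells across all samples.
    """
    if mode not in ("per_sample", "global"):
        raise ValidationError(f"unknown normalization mode {mode!r}")
    if not matrix.is_complete:
        raise StageOrderError(
            "matrix contains undetected wells; run impute_undetected before normalizing"
        )
    if not matrix.control_probe_ids:
        raise ValidationError("no control probes present; cannot compute ΔCt")
    controls = matrix.values.loc[list(matrix.control_probe_ids)]
    if mode == "per_sample":
        offset = controls.mean(axis=0)  # one scalar per sample
        values = matrix.values.sub(offset, axis=1)
    else:
        values = matrix.values - float(controls.to_numpy().mean())
    imputed = matrix.imputed
    if drop_controls:
        values = values.drop(index=list(matrix.control_probe_ids))
        if imputed is not None:
            imputed = imputed.drop(index=list(matrix.control_probe_ids))
        controls_out: tuple[str, ...] = ()
    else:
        controls_out = matrix.control_probe_ids
    return DeltaCtMatrix(
        values=values,
        normalization_mode=mode,
        control_probe_ids=controls_out,
        imputed=None if imputed is None else imputed.copy(),
    )


def fold_change_ddct(
    delta_ct_case,
    delta_ct_reference,
    *,
    case_imputed: bool = False,
    reference_imputed: bool = False,
) -> float:
    """Comparative-Ct fold change, 2^−(ΔCt_case − ΔCt_reference).

    Scalar or replicate (e.g. triplicate) inputs are accepted; replicates are
    averaged on the ΔCt scale before exponentiation.  A one-cycle lower ΔCt in
    the case doubles the fold change.
    """
    case = np.asarray(delta_ct_case, dtype=float).ravel()
    ref = np.asarray(delta_ct_reference, dtype=float).ravel()
    if case.size == 0 or ref.size == 0:
        raise ValidationError("fold_change_ddct requires at least one value per side")
    if not (np.isfinite(case).all() and np.isfinite(ref).all()):
        raise ValidationError("fold_change_ddct inputs must be finite")
    if case_imputed or reference_imputed:
        warnings.warn(
            "a ceiling-imputed well entered the fold-change computation; "
            "the fold change may be inflated",
            ImputedFoldChangeWarning,
            stacklevel=2,
        )
    ddct = case.mean() - ref.mean()
    return float(2.0 ** (-ddct))


# ---------------------------------------------------------------------------
# GCT 1.2 (GenePattern-style expression matrix)
# ---------------------------------------------------------------------------

def write_gct(values: pd.DataFrame, path: str | Path, descriptions: pd.Series | None = None) -> Path:
    """Write a probes × samples matrix as GCT 1.2 text."""
    path = Path(path)
    n_rows, n_cols = values.shape
    desc = (
        descriptions.reindex(values.index).fillna("na")
        if descriptions is not None
        else pd.Series("na", index=values.index)
    )
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_rows}\t{n_cols}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, values.columns)) + "\n")
        for probe in values.index:
            row = "\t".join(repr(float(v)) for v in values.loc[probe])
            fh.write(f"{probe}\t{desc.loc[probe]}\t{row}\n")
    return path


def read_gct(path: str | Path) -> pd.DataFrame:
    """Read a GCT 1.2 file back into a probes × samples DataFrame."""
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected '#1.2' header, got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t", index_col=0)
    df = body.drop(columns=["Description"]).astype(float)
    if df.shape != (n_rows, n_cols):
        raise FormatError(
            f"{path}: dimension line says {n_rows}×{n_cols}, body is {df.shape[0]}×{df.shape[1]}"
        )
    df.index.name = None
    return df
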
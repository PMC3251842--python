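"""Gene-signature containers, signature file IO, and LOOCV-driven reduction
of a candidate probe list to a compact predictor.

A *signature* is an ordered set of probe identifiers used jointly as a
classifier feature set.  The search strategy here evaluates nested prefixes of
a p-value-ranked candidate list: for every prefix length k the signature is
scored by leave-one-out cross-validated accuracy on the training samples,
with external-validation accuracy (when supplied) and then smaller k breaking
ties.  Exhaustive subset search over ~C(38, 13) ≈ 10^10 subsets is both
infeasible and unnecessary; the nested-prefix family keeps the search
deterministic and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import ValidationError

#: The published 13-miRNA erlotinib-sensitivity signature (hsa-mir identifiers).
ERLOTINIB_SIGNATURE_13 = (
    "hsa-mir-140-3p",
    "hsa-mir-628-5p",
    "hsa-mir-518f",
    "hsa-mir-636",
    "hsa-mir-301a",
    "hsa-mir-34c",
    "hsa-mir-224",
    "hsa-mir-197",
    "hsa-mir-205",
    "hsa-mir-135b",
    "hsa-mir-200b",
    "hsa-mir-200c",
    "hsa-mir-141",
)


@dataclass
class SignatureSet:
    """An ordered k-probe predictor.

    ``provenance`` records how the set arose: ``fixed`` (packaged published
    signature), ``searched`` (data-driven reduction), or ``planted``
    (simulation ground truth).  ``directions`` optionally maps each probe to
    ``up_in_sensitive`` / ``down_in_sensitive`` on the expression scale
    (up-regulated = lower ΔCt).
    """

    probe_ids: tuple[str, ...]
    provenance: str = "searched"
    directions: Mapping[str, str] | None = None
    selection_metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probe_ids = tuple(self.probe_ids)
        if len(self.probe_ids) == 0:
            raise ValidationError("a signature must contain at least one probe")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("signature probe ids must be distinct")

    @property
    def k(self) -> int:
        return len(self.probe_ids)

    def __iter__(self):
        return iter(self.probe_ids)

    def __contains__(self, probe: str) -> bool:
        return probe in self.probe_ids


def erlotinib_signature() -> SignatureSet:
    """The packaged published 13-miRNA signature of erlotinib sensitivity,
    for use with user-supplied expression data keyed on hsa-mir identifiers."""
    return SignatureSet(ERLOTINIB_SIGNATURE_13, provenance="fixed")


def read_signature_file(path: str | Path) -> SignatureSet:
    """Read one probe id per line; ``#`` starts a comment."""
    probes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            probes.append(line)
    return SignatureSet(tuple(probes), provenance="fixed")


def write_signature_file(signature: SignatureSet, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"# k={signature.k} provenance={signature.provenance}"]
    lines += list(signature.probe_ids)
    path.write_text("\n".join(lines) + "\n")
    return path


def reduce_signature(
    candidates: Sequence[str],
    train,
    labels,
    *,
    validation=None,
    validation_labels=None,
    k_max: int | None = None,
    variance_floor: float = 1e-8,
    return_path: bool = False,
):
    """Reduce an ordered candidate probe list to the best nested-prefix
    signature.

    Parameters
    ----------
    candidates : sequence of str
        Probe ids ordered by strength of differential-expression evidence
        (ascending p from the screen).
    train : DeltaCtMatrix
        Training expression; must contain every candidate probe.
    labels : mapping sample -> {'sensitive', 'resistant'}
    validation, validation_labels : optional
        External labelled expression used *only* to break ties in LOOCV
        accuracy, never for fitting, so the external-validation claim
        structure is preserved.
    k_max : int, optional
        Largest prefix length to evaluate (default: all candidates).

    Returns
    -------
    SignatureSet (and, if ``return_path``, a DataFrame of every evaluated
    prefix with its metrics).
    """
    from .dlda import fit_dlda, loocv, predict_batch

    candidates = list(candidates)
    if not candidates:
        raise ValidationError("candidate probe list is empty")
    if len(set(candidates)) != len(candidates):
        raise ValidationError("candidate probe ids must be distinct")
    missing = [p for p in candidates if p not in train.values.index]
    if missing:
        raise ValidationError(f"candidate probe(s) absent from training matrix: {', '.join(missing)}")
    if k_max is None:
        k_max = len(candidates)
    if not 1 <= k_max <= len(candidates):
        raise ValidationError("k_max must be between 1 and the number of candidates")
    use_validation = validation is not None
    if use_validation and validation_labels is None:
        raise ValidationError("validation matrix supplied without validation labels")

    rows = []
    best_key = None
    best = None
    for k in range(1, k_max + 1):
        sig = candidates[:k]
        cv = loocv(train, labels, sig, variance_floor=variance_floor)
        val_acc = float("nan")
        if use_validation:
            model = fit_dlda(train, labels, sig, variance_floor=variance_floor)
            preds = predict_batch(model, validation, actual=validation_labels)
            scored = preds.dropna(subset=["actual"])
            val_acc = float((scored["call"] == scored["actual"]).mean())
        rows.append({"k": k, "loocv_accuracy": cv.accuracy, "validation_accuracy": val_acc})
        # lexicographic: max LOOCV, then max validation, then smaller k
        key = (cv.accuracy, val_acc if use_validation else 0.0)
        if best_key is None or key > best_key:
            best_key = key
            best = rows[-1]

    metrics = {
        "loocv_accuracy": best["loocv_accuracy"],
        "k_evaluated": k_max,
    }
    if use_validation:
        metrics["validation_accuracy"] = best["validation_accuracy"]
    result = SignatureSet(
        tuple(candidates[: best["k"]]),
        provenance="searched",
        selection_metrics=metrics,
    )
    if return_path:
        return result, pd.DataFrame(rows)
    return result
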
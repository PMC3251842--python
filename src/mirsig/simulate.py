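"""Synthetic TaqMan-card experiment generator.

Emulates the study design the pipeline expects: a 381-feature low-density
qPCR card (378 assay miRNA probes + 3 endogenous-control wells) profiled on a
small training panel of erlotinib-sensitive and -resistant cell lines, plus a
validation cohort of further cell lines and primary/metastatic tumour
specimens.  A planted k-probe signature (11 probes up- and 2 down-regulated
in sensitive samples by default) carries the class effect; everything else is
noise.

Generative model (all on the Ct scale, where lower Ct = more transcript):

    Ct[j, s] = baseline_j + loading_s + effect[j, s] + eps[j, s]

* ``baseline_j`` ~ U(baseline_ct_range), drawn once per probe; control wells
  draw from the low (abundant) end of the range and carry no class effect.
* ``loading_s`` ~ N(0, sample_loading_sd): per-sample RNA input differences,
  exactly removed by per-sample ΔCt normalization.
* ``effect[j, s]`` = −effect_cycles for up-regulated planted probes in
  sensitive-profile samples (+effect_cycles for down-regulated ones), 0
  elsewhere.
* ``eps`` ~ N(0, noise_sd) independently per well (control wells included).

Optional departures from that model: ``tumor_purity`` < 1 attenuates the
class effect in tumour specimens (stromal dilution) and
``tumor_noise_multiplier`` > 1 inflates their noise (FFPE degradation); both
default to the neutral 1.0 so tumour wells follow the same generative law as
cell-line wells.

Wells drifting past ``dropout_ceiling`` cycles are undetected; wells within
five cycles of the ceiling drop out stochastically at ``dropout_slope``
probability per cycle, so higher-Ct (lower-abundance) probes drop out more.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .ct import CtMatrix, load_ct_table, write_ct_table
from .exceptions import ConfigurationError
from .signature import SignatureSet, read_signature_file, write_signature_file

CONTROL_NAMES = ("U6-snRNA", "RNU44", "RNU48")

#: Cycles below the dropout ceiling over which stochastic dropout ramps up.
DROPOUT_RAMP_CYCLES = 5.0


@dataclass
class SimulationConfig:
    """Parameters of one simulated card experiment.

    ``n_probes`` counts every card feature *including* the ``n_controls``
    control wells, so the default 381-feature card carries 378 assay probes —
    the pool from which random signatures are later drawn.  ``n_validation``
    gives the validation-cohort size per specimen category; the default
    (8 cell lines, 4 primary tumours, 4 metastatic tumours) mirrors a
    16-unknown validation design.  ``discordant_sample`` converts the last
    resistant training line into one whose signature expression follows the
    sensitive profile, the analogue of a resistant line carrying a
    sensitizing genotype.
    """

    n_probes: int = 381
    n_controls: int = 3
    n_sensitive_train: int = 4
    n_resistant_train: int = 4
    n_validation: Mapping[str, int] = field(
        default_factory=lambda: {"cell_line": 8, "primary": 4, "metastatic": 4}
    )
    signature_size: int = 13
    n_up_in_sensitive: int = 11
    n_down_in_sensitive: int = 2
    effect_cycles: float = 3.0
    noise_sd: float = 0.75
    baseline_ct_range: tuple[float, float] = (18.0, 32.0)
    dropout_ceiling: float = 40.0
    dropout_slope: float = 0.05
    discordant_sample: bool = False
    sample_loading_sd: float = 0.5
    tumor_purity: float = 1.0
    tumor_noise_multiplier: float = 1.0
    primary_sensitive_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        def fail(msg: str):
            raise ConfigurationError(msg)

        if self.n_up_in_sensitive + self.n_down_in_sensitive != self.signature_size:
            fail("n_up_in_sensitive + n_down_in_sensitive must equal signature_size")
        counts = {
            "n_probes": self.n_probes,
            "n_controls": self.n_controls,
            "n_sensitive_train": self.n_sensitive_train,
            "n_resistant_train": self.n_resistant_train,
            "signature_size": self.signature_size,
            "n_up_in_sensitive": self.n_up_in_sensitive,
            "n_down_in_sensitive": self.n_down_in_sensitive,
        }
        for name, v in counts.items():
            if v < 0:
                fail(f"{name} must be >= 0")
        for cat, v in dict(self.n_validation).items():
            if cat not in ("cell_line", "primary", "metastatic"):
                fail(f"unknown validation category {cat!r}")
            if v < 0:
                fail(f"n_validation[{cat!r}] must be >= 0")
        if self.signature_size < 1:
            fail("signature_size must be >= 1")
        if self.signature_size > self.n_probes - self.n_controls:
            fail("signature_size must not exceed the number of assay probes")
        if self.noise_sd <= 0:
            fail("noise_sd must be > 0")
        if self.effect_cycles < 0:
            fail("effect_cycles must be >= 0")
        lo, hi = self.baseline_ct_range
        if not (15.0 <= lo < hi <= 38.0):
            fail("baseline_ct_range must be an interval within [15, 38]")
        if not 0 < self.dropout_ceiling <= 40.0:
            fail("dropout_ceiling must lie in (0, 40]")
        if self.dropout_slope < 0:
            fail("dropout_slope must be >= 0")
        if self.sample_loading_sd < 0:
            fail("sample_loading_sd must be >= 0")
        if not 0 < self.tumor_purity <= 1:
            fail("tumor_purity must lie in (0, 1]")
        if self.tumor_noise_multiplier <= 0:
            fail("tumor_noise_multiplier must be > 0")
        if not 0 <= self.primary_sensitive_fraction <= 1:
            fail("primary_sensitive_fraction must lie in [0, 1]")


@dataclass
class CardDataset:
    """One simulated experiment: the raw Ct readout, per-sample annotations
    (label, tissue, specimen, cohort, and the generative ``true_profile``),
    and the planted signature."""

    ct: CtMatrix
    annotations: pd.DataFrame
    planted: SignatureSet

    @property
    def training_samples(self) -> list[str]:
        ann = self.annotations
        return list(ann.index[ann["cohort"] == "train"])

    @property
    def validation_samples(self) -> list[str]:
        ann = self.annotations
        return list(ann.index[ann["cohort"] == "validation"])

    @property
    def labels(self) -> pd.Series:
        return self.annotations["label"]

    def training_labels(self) -> pd.Series:
        return self.annotations.loc[self.training_samples, "label"]

    def validation_labels(self) -> pd.Series:
        return self.annotations.loc[self.validation_samples, "label"]


def _sample_plan(config: SimulationConfig) -> pd.DataFrame:
    """Build the per-sample design: id, label, tissue, specimen, cohort and
    the generative expression profile."""
    rows = []
    for i in range(config.n_sensitive_train):
        rows.append((f"sens-cl-{i + 1}", "sensitive", "lung", "cell_line", "train", "sensitive"))
    for i in range(config.n_resistant_train):
        profile = "resistant"
        if config.discordant_sample and i == config.n_resistant_train - 1:
            profile = "sensitive"  # resistant label, sensitive-like signature expression
        rows.append((f"res-cl-{i + 1}", "resistant", "lung", "cell_line", "train", profile))
    nv = dict(config.n_validation)
    n_cl = nv.get("cell_line", 0)
    n_cl_sens = n_cl // 2
    for i in range(n_cl):
        label = "sensitive" if i < n_cl_sens else "resistant"
        tissue = "lung" if i % 2 == 0 else "pancreas"
        rows.append((f"val-cl-{i + 1}", label, tissue, "cell_line", "validation", label))
    n_p = nv.get("primary", 0)
    n_p_sens = int(round(config.primary_sensitive_fraction * n_p))
    for i in range(n_p):
        label = "sensitive" if i < n_p_sens else "resistant"
        rows.append((f"primary-{i + 1}", label, "lung", "primary", "validation", label))
    for i in range(nv.get("metastatic", 0)):
        rows.append((f"met-{i + 1}", "resistant", "lung", "metastatic", "validation", "resistant"))
    plan = pd.DataFrame(
        rows, columns=["sample_id", "label", "tissue", "specimen", "cohort", "true_profile"]
    ).set_index("sample_id")
    return plan


def simulate_card_experiment(config: SimulationConfig | None = None, **overrides) -> CardDataset:
    """Simulate one card experiment under ``config`` (see module docstring
    for the generative model).  Identical config + seed gives a bit-identical
    dataset."""
    if config is None:
        config = SimulationConfig()
    if overrides:
        config = replace(config, **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_assay = config.n_probes - config.n_controls
    assay_ids = [f"hsa-mir-s{i + 1:04d}" for i in range(n_assay)]
    control_ids = list(CONTROL_NAMES[: config.n_controls])
    control_ids += [f"control-{i + 1}" for i in range(len(control_ids), config.n_controls)]
    probe_ids = assay_ids + control_ids

    plan = _sample_plan(config)
    n_samples = len(plan)

    lo, hi = config.baseline_ct_range
    baselines = np.empty(config.n_probes)
    baselines[:n_assay] = rng.uniform(lo, hi, size=n_assay)
    # controls are abundant, stable transcripts: low-Ct end of the range
    baselines[n_assay:] = rng.uniform(lo, min(lo + 2.0, hi), size=config.n_controls)

    sig_idx = rng.choice(n_assay, size=config.signature_size, replace=False)
    directions = {}
    effect_sign = np.zeros(config.n_probes)
    for rank, j in enumerate(sig_idx):
        up = rank < config.n_up_in_sensitive
        directions[assay_ids[j]] = "up_in_sensitive" if up else "down_in_sensitive"
        effect_sign[j] = -1.0 if up else 1.0  # up-regulated = lower Ct

    loading = rng.normal(0.0, config.sample_loading_sd, size=n_samples)
    is_tumor = plan["specimen"].isin(["primary", "metastatic"]).to_numpy()
    is_sensitive_profile = (plan["true_profile"] == "sensitive").to_numpy()
    effect_scale = np.where(is_tumor, config.tumor_purity, 1.0) * config.effect_cycles
    noise_scale = np.where(is_tumor, config.tumor_noise_multiplier, 1.0) * config.noise_sd

    effect = np.outer(effect_sign, np.where(is_sensitive_profile, effect_scale, 0.0))
    eps = rng.normal(0.0, 1.0, size=(config.n_probes, n_samples)) * noise_scale[None, :]
    ct = baselines[:, None] + loading[None, :] + effect + eps
    ct = np.clip(ct, 0.0, None)

    ramp_start = config.dropout_ceiling - DROPOUT_RAMP_CYCLES
    p_drop = np.clip(config.dropout_slope * (ct - ramp_start), 0.0, 1.0)
    undetected = (ct > config.dropout_ceiling) | (rng.random(ct.shape) < p_drop)

    sample_ids = pd.Index(plan.index.to_list())
    values = pd.DataFrame(ct, index=probe_ids, columns=sample_ids).mask(
        pd.DataFrame(undetected, index=probe_ids, columns=sample_ids)
    )
    detected = pd.DataFrame(~undetected, index=probe_ids, columns=sample_ids)
    matrix = CtMatrix(values=values, detected=detected, control_probe_ids=tuple(control_ids))
    planted = SignatureSet(
        tuple(assay_ids[j] for j in sig_idx), provenance="planted", directions=directions
    )
    return CardDataset(ct=matrix, annotations=plan, planted=planted)


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

def write_fixture_bundle(dataset: CardDataset, directory: str | Path) -> dict[str, Path]:
    """Write the Ct table, sample annotations, control list and planted
    signature as plain TSV/text in the formats the processing stages consume.
    The round trip through :func:`read_fixture_bundle` is lossless up to
    decimal text representation (written with ``repr``, hence exact)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "ct_table": directory / "ct_table.tsv",
        "annotations": directory / "annotations.tsv",
        "controls": directory / "controls.txt",
        "signature": directory / "planted_signature.txt",
    }
    write_ct_table(dataset.ct, paths["ct_table"])
    dataset.annotations.to_csv(paths["annotations"], sep="\t")
    paths["controls"].write_text("\n".join(dataset.ct.control_probe_ids) + "\n")
    write_signature_file(dataset.planted, paths["signature"])
    return paths


def read_fixture_bundle(directory: str | Path) -> CardDataset:
    """Reload a fixture bundle written by :func:`write_fixture_bundle`."""
    directory = Path(directory)
    controls = [
        line.strip()
        for line in (directory / "controls.txt").read_text().splitlines()
        if line.strip()
    ]
    ct = load_ct_table(directory / "ct_table.tsv", control_probes=controls)
    annotations = pd.read_csv(directory / "annotations.tsv", sep="\t", index_col=0)
    sig = read_signature_file(directory / "planted_signature.txt")
    planted = SignatureSet(sig.probe_ids, provenance="planted")
    return CardDataset(ct=ct, annotations=annotations, planted=planted)
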
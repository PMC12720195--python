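"""Classify dual-stress (acidosis x hypoxia) omics responses.

If acidosis and hypoxia acted independently on a protein, its log2
abundance response to the combined treatment would equal the sum of the
single-stress responses.  The departure

    delta = r_combo - (r_acid + r_hypoxia)

classifies each protein: synergistic when the combined response exceeds the
expectation by more than the cutoff (default +0.5 log2 units), antagonistic
when it falls short by more than the cutoff, additive otherwise.  Records
whose responses are all small are reported as non-significant; since the
operational significance rule of the original analysis is not published,
this package uses a transparent magnitude rule (all of |r_acid|,
|r_hypoxia|, |r_combo| and |delta| below ``significance_cutoff``) and
exposes the cutoff.

A synthetic proteome generator emulates a ~9,000-protein table with planted
class labels so the classifier can be validated without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InteractionRecord",
    "SyntheticProteomeSpec",
    "classify",
    "classify_table",
    "generate_synthetic_proteome",
    "CLASSES",
]

CLASSES = ("additive", "synergistic", "antagonistic", "nonsignificant")

REQUIRED_COLUMNS = ("protein_id", "log2fc_acid", "log2fc_hypoxia", "log2fc_combo")


@dataclass(frozen=True)
class InteractionRecord:
    """Per-protein log2 responses and their interaction class."""

    protein_id: str
    r_acid: float
    r_hypoxia: float
    r_combo: float

    @property
    def expected(self) -> float:
        return self.r_acid + self.r_hypoxia

    @property
    def delta(self) -> float:
        return self.r_combo - self.expected


def classify(
    record: InteractionRecord,
    interaction_cutoff: float = 0.5,
    significance_cutoff: float = 0.5,
) -> str:
    """Class of a single record; see module docstring for the rule."""
    vals = (record.r_acid, record.r_hypoxia, record.r_combo)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError(f"non-finite response in record {record.protein_id!r}")
    delta = record.delta
    if (
        max(abs(v) for v in vals) < significance_cutoff
        and abs(delta) < significance_cutoff
    ):
        return "nonsignificant"
    if delta > interaction_cutoff:
        return "synergistic"
    if delta < -interaction_cutoff:
        return "antagonistic"
    return "additive"


def classify_table(
    table: pd.DataFrame,
    interaction_cutoff: float = 0.5,
    significance_cutoff: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every protein in a response table.

    ``table`` needs columns protein_id, log2fc_acid, log2fc_hypoxia,
    log2fc_combo.  Rows with missing values are skipped (their count is
    reported under ``"skipped"``).  Returns the annotated table (``expected``,
    ``delta``, ``interaction_class`` columns added) and a counts dict that
    also reports ``frac_nonadditive_of_significant``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks required columns: {missing}")
    df = table.copy()
    resp = df[["log2fc_acid", "log2fc_hypoxia", "log2fc_combo"]].astype(float)
    ok = np.isfinite(resp).all(axis=1)
    n_skipped = int((~ok).sum())
    df = df.loc[ok].copy()
    r_a = df["log2fc_acid"].to_numpy(float)
    r_h = df["log2fc_hypoxia"].to_numpy(float)
    r_c = df["log2fc_combo"].to_numpy(float)
    expected = r_a + r_h
    delta = r_c - expected

    small = (
        (np.abs(r_a) < significance_cutoff)
        & (np.abs(r_h) < significance_cutoff)
        & (np.abs(r_c) < significance_cutoff)
        & (np.abs(delta) < significance_cutoff)
    )
    cls = np.where(
        small,
        "nonsignificant",
        np.where(
            delta > interaction_cutoff,
            "synergistic",
            np.where(delta < -interaction_cutoff, "antagonistic", "additive"),
        ),
    )
    df["expected"] = expected
    df["delta"] = delta
    df["interaction_class"] = cls

    counts: dict[str, int | float] = {c: int((cls == c).sum()) for c in CLASSES}
    counts["skipped"] = n_skipped
    n_sig = len(df) - counts["nonsignificant"]
    counts["frac_nonadditive_of_significant"] = (
        float((counts["synergistic"] + counts["antagonistic"]) / n_sig)
        if n_sig
        else float("nan")
    )
    return df, counts


@dataclass
class SyntheticProteomeSpec:
    """Recipe for a synthetic dual-stress proteome with planted classes.

    Defaults emulate the scale and class mix of a published SW1222
    colorectal-cancer proteomic screen (~9.4k proteins; a majority of
    responses non-significant, additive the largest significant class,
    antagonistic more common than synergistic).
    """

    n_proteins: int = 9354
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "additive": 0.279,
            "antagonistic": 0.088,
            "synergistic": 0.061,
            "nonsignificant": 0.572,
        }
    )
    effect_low: float = 0.8  # |single-stress response| range for significant rows
    effect_high: float = 2.5
    interaction_low: float = 0.7  # |delta| planted for synergy/antagonism
    interaction_high: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1 (got {total})")
        unknown = set(self.class_fractions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in fractions: {unknown}")


def generate_synthetic_proteome(spec: SyntheticProteomeSpec) -> pd.DataFrame:
    """Draw a response table with known (planted) interaction classes.

    At ``noise_sd`` 0 the classifier recovers the planted labels exactly;
    the ``planted_class`` column allows recovery tests at any noise level.
    """
    rng = np.random.default_rng(spec.seed)
    counts = {c: int(round(spec.class_fractions.get(c, 0.0) * spec.n_proteins)) for c in CLASSES}
    counts["additive"] += spec.n_proteins - sum(counts.values())  # rounding slack

    rows_cls: list[str] = []
    r_a = np.empty(spec.n_proteins)
    r_h = np.empty(spec.n_proteins)
    r_c = np.empty(spec.n_proteins)
    i = 0

    def draw_effect(n: int) -> np.ndarray:
        mag = rng.uniform(spec.effect_low, spec.effect_high, n)
        return mag * rng.choice([-1.0, 1.0], n)

    for cls in CLASSES:
        n = counts[cls]
        sl = slice(i, i + n)
        if cls == "nonsignificant":
            # everything comfortably inside the significance box
            r_a[sl] = rng.uniform(-0.3, 0.3, n)
            r_h[sl] = rng.uniform(-0.3, 0.3, n)
            r_c[sl] = np.clip(
                r_a[sl] + r_h[sl] + rng.uniform(-0.15, 0.15, n), -0.45, 0.45
            )
        else:
            r_a[sl] = draw_effect(n)
            r_h[sl] = draw_effect(n)
            if cls == "additive":
                delta = rng.uniform(-0.4, 0.4, n)
            elif cls == "synergistic":
                delta = rng.uniform(spec.interaction_low, spec.interaction_high, n)
            else:  # antagonistic
                delta = -rng.uniform(spec.interaction_low, spec.interaction_high, n)
            r_c[sl] = r_a[sl] + r_h[sl] + delta
        rows_cls.extend([cls] * n)
        i += n

    if spec.noise_sd > 0:
        r_a = r_a + rng.normal(0.0, spec.noise_sd, spec.n_proteins)
        r_h = r_h + rng.normal(0.0, spec.noise_sd, spec.n_proteins)
        r_c = r_c + rng.normal(0.0, spec.noise_sd, spec.n_proteins)

    df = pd.DataFrame(
        {
            "protein_id": [f"P{k:05d}" for k in range(spec.n_proteins)],
            "log2fc_acid": r_a,
            "log2fc_hypoxia": r_h,
            "log2fc_combo": r_c,
            "planted_class": rows_cls,
        }
    )
    return df.sample(frac=1.0, random_state=spec.seed).reset_index(drop=True)
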
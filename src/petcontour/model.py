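"""Study-level model object tying the pipeline together.

:class:`ContouringValidation` plays the role a model class plays in
statsmodels: it is built from data (one or more subjects, each a PET
volume with its registered histology pairs), and :meth:`fit` runs
threshold derivation, GTA classification, per-pair ROC analysis and
clustered aggregation, returning a :class:`ContouringValidationResults`
carrying the estimates, their uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aggregate as agg
from .contouring import (
    DEFAULT_LIVER_MULTIPLES,
    DEFAULT_PERCENTS,
    ThresholdSpec,
    build_spectrum,
    make_gta,
)
from .dataio import PetVolume
from .phantom import PhantomConfig, generate_phantom, tumor_search_region
from .registration import RegisteredPair, build_pair
from .validation import classify_pair, roc_for_pair

__all__ = ["SubjectData", "ContouringValidation", "ContouringValidationResults"]


@dataclass
class SubjectData:
    """One imaged animal: a volume, its search region, liver ROI and pairs."""

    subject_id: str
    volume: PetVolume
    tumor_region: np.ndarray
    liver_center_mm: np.ndarray
    pairs: list[RegisteredPair] = field(default_factory=list)


class ContouringValidation:
    """Validation of single-value PET thresholds against histology.

    Parameters
    ----------
    subjects
        The study cohort. Thresholds are derived per subject (C_max,
        C_peak and liver statistics are animal-specific), then every
        threshold is tested on every registered pair of that subject.
    percents, liver_multiples
        Threshold grids for the percent-of-C_max / C_peak methods and the
        liver-multiple method.
    """

    def __init__(
        self,
        subjects: list[SubjectData],
        percents: tuple[float, ...] = DEFAULT_PERCENTS,
        liver_multiples: tuple[float, ...] = DEFAULT_LIVER_MULTIPLES,
    ) -> None:
        if not subjects:
            raise ValueError("need at least one subject")
        self.subjects = subjects
        self.percents = tuple(percents)
        self.liver_multiples = tuple(liver_multiples)

    @classmethod
    def from_phantoms(
        cls,
        configs: list[PhantomConfig],
        search_margin_mm: float = 3.0,
        **kwargs,
    ) -> "ContouringValidation":
        """Generate phantoms and register their histology sections."""
        subjects = []
        for i, config in enumerate(configs):
            volume, truth = generate_phantom(config)
            manifest = truth.manifest()
            pairs = [
                build_pair(volume, truth.section(e.section_id), e)
                for e in manifest.entries
            ]
            subjects.append(
                SubjectData(
                    subject_id=f"rat{i + 1}",
                    volume=volume,
                    tumor_region=tumor_search_region(truth, search_margin_mm),
                    liver_center_mm=np.asarray(config.liver.center_mm),
                    pairs=pairs,
                )
            )
        return cls(subjects, **kwargs)

    def spectra(self, subject: SubjectData) -> list[ThresholdSpec]:
        """Pooled threshold spectrum (all three methods) for one subject."""
        specs = build_spectrum(
            "cmax_pct", subject.volume, tumor_region=subject.tumor_region,
            percents=self.percents,
        )
        specs += build_spectrum(
            "cpeak_pct", subject.volume, tumor_region=subject.tumor_region,
            percents=self.percents,
        )
        specs += build_spectrum(
            "liver_multiple", subject.volume,
            liver_center_mm=subject.liver_center_mm,
            liver_multiples=self.liver_multiples,
        )
        return specs

    def fit(self, n_boot: int = 10_000, seed: int | None = None) -> "ContouringValidationResults":
        """Run the full classification and aggregation.

        ``seed`` drives only the bootstrap resampling; everything else is
        deterministic given the input data.
        """
        records = []
        auc_records = []
        roc_curves = []
        for subject in self.subjects:
            specs = self.spectra(subject)
            for pair in subject.pairs:
                # Cluster = sectioning position, globally unique per subject.
                cluster = f"{subject.subject_id}:{pair.cluster_id}"
                pair_id = f"{subject.subject_id}:{pair.section_id}"
                for spec in specs:
                    c = classify_pair(pair, make_gta(pair.pet_slice, spec, pair.section_id))
                    records.append(
                        {
                            "subject_id": subject.subject_id,
                            "section_id": pair_id,
                            "cluster_id": cluster,
                            "method": spec.method,
                            "parameter": spec.parameter,
                            "absolute_counts": spec.absolute_counts,
                            "tp": c.tp_px,
                            "fn": c.fn_px,
                            "tn": c.tn_px,
                            "fp": c.fp_px,
                            "oe": c.oe_px,
                            "wta": c.wta_px,
                            "sensitivity": c.sensitivity,
                            "specificity": c.specificity,
                            "oe_ratio": c.oe_ratio,
                        }
                    )
                curve = roc_for_pair(pair, specs)
                roc_curves.append(curve)
                if curve.defined:
                    auc_records.append(
                        {"section_id": pair_id, "cluster_id": cluster, "auc": curve.auc}
                    )
        per_pair = pd.DataFrame(records)
        roc_auc = pd.DataFrame(auc_records)
        aggregate = agg.summarize(per_pair, roc_auc, n_boot=n_boot, seed=seed)
        return ContouringValidationResults(
            model=self,
            per_pair=per_pair,
            roc_auc=roc_auc,
            roc_curves=roc_curves,
            aggregate=aggregate,
        )


class ContouringValidationResults:
    """Fitted results: per-pair metrics, ROC curves and aggregate table."""

    def __init__(self, model, per_pair, roc_auc, roc_curves, aggregate) -> None:
        self.model = model
        self.per_pair = per_pair
        self.roc_auc = roc_auc
        self.roc_curves = roc_curves
        self.aggregate = aggregate

    @property
    def n_pairs(self) -> int:
        return int(self.per_pair["section_id"].nunique())

    @property
    def mean_auc(self) -> float:
        row = self.aggregate[self.aggregate["metric"] == "auc"]
        return float(row["mean"].iloc[0]) if len(row) else float("nan")

    @property
    def auc_ci(self) -> tuple[float, float]:
        row = self.aggregate[self.aggregate["metric"] == "auc"]
        if not len(row):
            return (float("nan"), float("nan"))
        return float(row["ci_low"].iloc[0]), float(row["ci_high"].iloc[0])

    def method_table(self, method: str) -> pd.DataFrame:
        """Wide per-threshold table for one method (layout of a results table)."""
        sub = self.aggregate[self.aggregate["method"] == method]
        wide = sub.pivot(index="parameter", columns="metric",
                         values=["mean", "ci_low", "ci_high"])
        cols = []
        for metric in ("sensitivity", "specificity", "oe_ratio"):
            for stat in ("mean", "ci_low", "ci_high"):
                cols.append((f"{metric}_{stat}", wide[(stat, metric)]))
        return pd.DataFrame(dict(cols))

    def summary(self) -> str:
        lines = [
            "Single-value-threshold PET contouring vs histology",
            "=" * 58,
            f"subjects: {len(self.model.subjects)}   image pairs: {self.n_pairs}",
            f"mean per-pair AUC: {self.mean_auc:.3f}"
            f"  (95% CI {self.auc_ci[0]:.3f}-{self.auc_ci[1]:.3f})",
            "",
        ]
        for method, label in (
            ("cmax_pct", "Method I - % of C_max"),
            ("cpeak_pct", "Method II - % of C_peak"),
            ("liver_multiple", "Method III - k x C_liver_mean + 2 x SD"),
        ):
            if not (self.aggregate["method"] == method).any():
                continue
            t = self.method_table(method)
            lines.append(label)
            lines.append("-" * 58)
            header = f"{'param':>6} {'sens':>7} {'(95% CI)':>15} {'spec':>7} {'oe/wta':>8}"
            lines.append(header)
            for p, row in t.iterrows():
                lines.append(
                    f"{p:>6g} {row['sensitivity_mean']:>7.3f} "
                    f"({row['sensitivity_ci_low']:.3f}-{row['sensitivity_ci_high']:.3f}) "
                    f"{row['specificity_mean']:>7.3f} {row['oe_ratio_mean']:>8.3f}"
                )
            lines.append("")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    # plots
    # ------------------------------------------------------------------

    def plot_roc_grid(self, ncols: int = 6):
        """Grid of per-pair ROC curves (one panel per image pair)."""
        import matplotlib.pyplot as plt

        curves = [c for c in self.roc_curves if c.defined]
        nrows = max(1, int(np.ceil(len(curves) / ncols)))
        fig, axes = plt.subplots(nrows, ncols, figsize=(2.2 * ncols, 2.2 * nrows),
                                 squeeze=False)
        for ax in axes.ravel():
            ax.set_axis_off()
        for ax, curve in zip(axes.ravel(), curves):
            ax.set_axis_on()
            ax.plot(curve.points[:, 0], curve.points[:, 1], "o-", ms=2, lw=1)
            ax.plot([0, 1], [0, 1], "k:", lw=0.5)
            ax.set_title(f"{curve.section_id}\nAUC={curve.auc:.3f}", fontsize=6)
            ax.set_xticks([]), ax.set_yticks([])
        fig.tight_layout()
        return fig

    def plot_threshold_curves(self, method: str = "cmax_pct"):
        """Mean sensitivity and overestimation ratio vs threshold parameter."""
        import matplotlib.pyplot as plt

        t = self.method_table(method)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(t.index, t["sensitivity_mean"], "o-", label="sensitivity")
        ax.fill_between(t.index, t["sensitivity_ci_low"], t["sensitivity_ci_high"], alpha=0.2)
        ax.plot(t.index, t["oe_ratio_mean"], "s-", label="GTA_OE / WTA_H")
        ax.fill_between(t.index, t["oe_ratio_ci_low"], t["oe_ratio_ci_high"], alpha=0.2)
        ax.set_xlabel("threshold parameter")
        ax.set_ylabel("mean across pairs")
        ax.set_title(method)
        ax.legend()
        fig.tight_layout()
        return fig
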
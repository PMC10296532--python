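"""End-to-end orchestration of the primary and confirmation analyses.

``run_primary`` executes the full primary-screen chain in fixed order —
read or simulate plates, image-flag exclusion, control-outlier removal,
normalization, QC report, vehicle-toxicity filter, %E-DI, threshold, hit
calls, summary — logging each stage's in/out counts. ``run_confirmation``
averages the two confirmation screens, fits the 4PL per compound and cell
line, adjudicates IC50s, and triages leads. ``demo`` chains both on
synthetic data.

Every constant of the analysis lives in :class:`PipelineConfig` with its
conventional default (toxicity cutoff 0.5, outlier rule 3 SD, threshold
multiplier 2.5, lead cutoff 1 µM, gates Z' >= 0.5 and %CV < 25), is
overridable, and is logged, as is the %E-DI form and the applied
threshold, so no interpretation choice is ever silent.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import dose_response, hit_calling, normalize_filter, qc_metrics
from .plate_model import (
    ScreenDataset,
    read_count_table,
    read_plate_layout,
    write_count_table,
)
from .synthetic_screen import (
    DoseResponseTruth,
    GeneratorConfig,
    simulate_confirmation_screen,
    simulate_primary_screen,
    write_truth_ledger,
)

logger = logging.getLogger("estroscreen")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and plate."""


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    # inputs: either file paths or a generator config
    layout_path: Optional[str] = None
    counts_path: Optional[str] = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # analysis constants
    edi_form: str = "inhibition"
    threshold_mode: str = "derived"  # "derived" or "fixed:<value>"
    threshold_multiplier: float = hit_calling.DEFAULT_THRESHOLD_MULTIPLIER
    toxicity_cutoff: float = normalize_filter.TOXICITY_CUTOFF
    outlier_k: float = normalize_filter.OUTLIER_K
    lead_cutoff_uM: float = dose_response.LEAD_IC50_CUTOFF_UM
    zprime_gate: float = qc_metrics.ZPRIME_GATE
    cv_gate: float = qc_metrics.CV_GATE
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if isinstance(self.generator, dict):
            gen = dict(self.generator)
            for key in ("cell_lines", "hit_inhibition_range",
                        "qc_positive_compounds", "qc_negative_compounds"):
                if key in gen and isinstance(gen[key], list):
                    gen[key] = tuple(gen[key])
            self.generator = GeneratorConfig(**gen)
        if self.edi_form not in hit_calling.EDI_FORMS:
            raise PipelineError(f"unknown edi_form {self.edi_form!r}")
        self.threshold_override  # validates threshold_mode

    @property
    def threshold_override(self) -> Optional[float]:
        if self.threshold_mode == "derived":
            return None
        if self.threshold_mode.startswith("fixed:"):
            return float(self.threshold_mode.split(":", 1)[1])
        raise PipelineError(
            f"threshold_mode must be 'derived' or 'fixed:<value>', got {self.threshold_mode!r}"
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class PrimaryResult:
    dataset: ScreenDataset
    qc_report: pd.DataFrame
    hit_table: pd.DataFrame
    threshold: hit_calling.HitThreshold
    summary: hit_calling.ScreenSummary


def _load_dataset(config: PipelineConfig) -> ScreenDataset:
    if config.counts_path is None:
        return simulate_primary_screen(config.generator)
    counts_path = Path(config.counts_path)
    if not counts_path.exists():
        raise PipelineError(f"stage read: counts file not found: {counts_path}")
    if config.layout_path is None:
        raise PipelineError("stage read: a layout file is required with counts input")
    layout_path = Path(config.layout_path)
    if not layout_path.exists():
        raise PipelineError(f"stage read: layout file not found: {layout_path}")
    layout = read_plate_layout(layout_path)
    plates = read_count_table(counts_path)
    layouts = {layout.plate_id: layout}
    pairing = {}
    by_key: dict[tuple[str, str], dict[str, object]] = {}
    for plate in plates:
        by_key.setdefault((layout.plate_id, plate.cell_line_id), {})[plate.condition] = plate
    for key, pair in by_key.items():
        if set(pair) != {"vehicle", "estrogen"}:
            raise PipelineError(
                f"stage read: cell line {key[1]!r} lacks a vehicle/estrogen plate pair"
            )
        pairing[key] = (pair["vehicle"], pair["estrogen"])
    return ScreenDataset(layouts=layouts, plates=plates, pairing=pairing)


def _paired_viability(
    dataset: ScreenDataset, outlier_k: float
) -> pd.DataFrame:
    """Normalized (alpha, beta) per compound per cell line.

    With a compound present on several plates for one line, replicate
    values are averaged; a missing vehicle measurement leaves alpha NaN.
    """
    records: list[dict] = []
    for (layout_id, line), (veh_plate, est_plate) in dataset.pairing.items():
        layout = dataset.layouts[layout_id]
        compound_map = layout.compound_wells()
        try:
            norm_veh = normalize_filter.normalize_plate(veh_plate, layout, outlier_k)
            norm_est = normalize_filter.normalize_plate(est_plate, layout, outlier_k)
        except normalize_filter.NormalizationError as exc:
            raise PipelineError(f"stage normalize: plate pair ({layout_id}, {line}): {exc}")
        for addr, cid in compound_map.items():
            records.append(
                {
                    "compound_id": cid,
                    "cell_line": line,
                    "alpha": norm_veh.normalized.get(addr, float("nan")),
                    "beta": norm_est.normalized.get(addr, float("nan")),
                }
            )
    df = pd.DataFrame(records)
    return (
        df.groupby(["compound_id", "cell_line"], as_index=False)[["alpha", "beta"]]
        .mean()
    )


def run_primary(config: PipelineConfig) -> PrimaryResult:
    """Primary screen: normalize, QC, triage, %E-DI, threshold, hits."""
    dataset = _load_dataset(config)
    n_pairs = len(dataset.pairing)
    logger.info("primary: %d plate pairs, %d raw plates", n_pairs, len(dataset.plates))

    try:
        qc_report = qc_metrics.screen_qc_report(dataset)
    except qc_metrics.QCError as exc:
        raise PipelineError(f"stage qc: {exc}")
    viability = _paired_viability(dataset, config.outlier_k)
    logger.info("normalize: %d (compound, line) viability pairs", len(viability))

    filtered = normalize_filter.vehicle_toxicity_filter(viability, config.toxicity_cutoff)
    counts = filtered["status"].value_counts().to_dict()
    logger.info("toxicity filter: %s", counts)

    edi_table = hit_calling.build_edi_table(filtered, form=config.edi_form)
    values = edi_table["edi"].dropna()
    threshold = hit_calling.derive_threshold(
        values,
        multiplier=config.threshold_multiplier,
        override=config.threshold_override,
    )
    logger.info(
        "threshold (%s form): derived %.2f, applied %.2f",
        config.edi_form, threshold.derived, threshold.applied,
    )
    hit_table = hit_calling.call_hits(edi_table, threshold)
    summary = hit_calling.summarize_screen(hit_table, threshold)
    # stage-count conservation: nothing silently dropped
    assert summary.n_excluded_toxicity + summary.n_analyzed + summary.n_unevaluable == summary.n_library
    if config.output_dir:
        _write_primary_outputs(config, dataset, qc_report, hit_table, summary)
    return PrimaryResult(
        dataset=dataset,
        qc_report=qc_report,
        hit_table=hit_table,
        threshold=threshold,
        summary=summary,
    )


def _write_primary_outputs(config, dataset, qc_report, hit_table, summary) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_table(dataset.plates, out / "counts.csv")
    if dataset.truth is not None:
        write_truth_ledger(dataset.truth, out / "truth_ledger.csv")
    qc_report.to_csv(out / "qc_report.csv", index=False)
    hit_table.to_csv(out / "hit_table.csv", index=False)
    (out / "summary.txt").write_text(summary.to_text() + "\n")


@dataclass
class ConfirmationResult:
    fits: pd.DataFrame
    lead_table: pd.DataFrame
    categories: dict[str, int]


def run_confirmation(
    config: PipelineConfig,
    doses: Optional[pd.DataFrame] = None,
    truths: Optional[list[DoseResponseTruth]] = None,
) -> ConfirmationResult:
    """Confirmation qHTS: average screens, fit, adjudicate, triage leads.

    ``doses`` is a measured tidy two-screen table; alternatively ``truths``
    are simulated under the config's generator. An empty pick list yields
    an empty result.
    """
    if doses is None:
        if truths is None:
            raise PipelineError("stage confirm: need a dose table or simulation truths")
        doses = simulate_confirmation_screen(truths, config.generator)
    if doses.empty:
        empty = pd.DataFrame(columns=["compound_id", "cell_line", "ic50", "status"])
        return ConfirmationResult(fits=empty, lead_table=pd.DataFrame(), categories={})
    fits = dose_response.fit_confirmation_table(doses)
    fit_frame = dose_response.fits_to_frame(fits)
    outcomes = fit_frame[["compound_id", "cell_line", "ic50"]]
    lead_table = dose_response.designate_leads(outcomes, cutoff_uM=config.lead_cutoff_uM)
    categories = dose_response.categorize_leads(lead_table)
    logger.info("confirmation: %d fits, categories %s", len(fits), categories)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        fit_frame.to_csv(out / "confirmation_fits.csv", index=False)
        lead_table.to_csv(out / "lead_table.csv", index=False)
    return ConfirmationResult(fits=fit_frame, lead_table=lead_table, categories=categories)


def truths_from_primary(result: PrimaryResult, config: PipelineConfig) -> list[DoseResponseTruth]:
    """4PL truths for the hit compounds of a synthetic primary screen.

    The confirmation-truth IC50 is chosen consistently with the primary
    screen's programmed effect: with top 100, bottom 0 and Hill slope 1,
    a compound whose estrogen-condition survival fraction at the 10 µM
    screening dose is s has IC50 = 10 * s / (1 - s) µM.
    """
    if result.dataset.truth is None:
        raise PipelineError("stage confirm: primary dataset carries no truth ledger")
    truth = result.dataset.truth.set_index(["compound_id", "cell_line"])
    hits = result.hit_table[result.hit_table["is_hit"]]
    out = []
    for rec in hits.itertuples(index=False):
        t = truth.loc[(rec.compound_id, rec.cell_line)]
        s = max(min(t["true_estrogen_effect"] / t["true_vehicle_effect"], 0.99), 1e-4)
        ic50 = 10.0 * s / (1.0 - s)
        out.append(
            DoseResponseTruth(
                compound_id=rec.compound_id,
                cell_line_id=rec.cell_line,
                top=100.0,
                bottom=0.0,
                log10_ic50=math.log10(ic50),
                hill=1.0,
            )
        )
    return out


def demo(seed: int = 1, output_dir: Optional[str] = None) -> tuple[PrimaryResult, ConfirmationResult]:
    """Full synthetic end-to-end run: primary screen then confirmation.

    Deterministic in ``seed``: identical seeds give byte-identical output
    files.
    """
    generator = GeneratorConfig(seed=seed)
    config = PipelineConfig(generator=generator, seed=seed, output_dir=output_dir)
    primary = run_primary(config)
    truths = truths_from_primary(primary, config)
    confirmation = run_confirmation(config, truths=truths)
    if output_dir:
        summary_path = Path(output_dir) / "demo_report.txt"
        lines = [
            primary.summary.to_text(),
            "",
            qc_metrics.qc_report_summary(primary.qc_report),
            "",
            f"confirmation follow-up: {len(truths)} (compound, line) series",
            f"lead categories: {confirmation.categories}",
        ]
        summary_path.write_text("\n".join(lines) + "\n")
    return primary, confirmation
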
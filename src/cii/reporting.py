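"""Value Matrix plot-data export and the end-to-end pipeline.

Plot output is declarative JSON — positions, colours, shade tiers, sizes —
rather than rendered images, so it is bit-exact testable; a thin optional
renderer can draw it.  Each circle stands for one (treatment, square) with
qualifying evidence: colour encodes the modality, shade the evidence
strength tier, and size the share of patients currently offered the
treatment (small/medium/large for some/most/all).
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel

from .errors import StageError
from .escore import (
    CustomWeights,
    compute_escore_series,
    config_fingerprint,
)
from .hierarchy import (
    EvidenceHierarchy,
    ScoringConfig,
    evidence_weight,
    qualifies,
    strength_tier,
)
from .models import Modality, PatientShare, Query
from .release import reversal_stats
from .store import EvidenceStore
from .value_matrix import (
    MatrixLayout,
    TreatmentGoalPath,
    ValueMatrix,
    resolve_square,
)

MODALITY_COLOURS = {
    Modality.surgery: "blue",
    Modality.radiotherapy: "green",
    Modality.chemotherapy: "brown",
    Modality.immunotherapy: "gray",
    Modality.group: "purple",
    Modality.other: "pink",
}

_SIZE_FOR_SHARE = {
    PatientShare.some: "small",
    PatientShare.most: "medium",
    PatientShare.all: "large",
}


class PlotCircle(BaseModel):
    """One treatment's presence in one matrix square at a given date."""

    treatment_id: str
    square: str
    modality_colour: str
    shade_tier: int
    size_class: str
    cumulative_weight: float
    as_of_date: datetime.date


def matrix_plot_data(
    query: Query,
    as_of_date: datetime.date,
    store: EvidenceStore,
    hierarchy: EvidenceHierarchy,
    layout: MatrixLayout,
    cfg: ScoringConfig,
    paths: Sequence[TreatmentGoalPath] = (),
) -> tuple[list[PlotCircle], list[TreatmentGoalPath]]:
    """Circles for every (treatment, square) with qualifying evidence dated
    on or before ``as_of_date``, plus pass-through goal paths.

    Shade comes from the strength tier of the cumulative qualifying
    evidence weight in that square; size from the treatment's patient-share
    history (treatments without a share entry yet default to small).
    """
    cumulative: dict[tuple[str, str], float] = {}
    for piece in store.query_pieces(query):
        if store.piece_date(piece) > as_of_date:
            continue
        if not qualifies(piece, cfg):
            continue
        square = resolve_square(piece.disease_state, piece.therapeutic_goal, layout)
        key = (piece.treatment_id, square)
        cumulative[key] = cumulative.get(key, 0.0) + evidence_weight(
            piece, hierarchy, store=store
        )
    circles = []
    for (treatment_id, square) in sorted(cumulative):
        treatment = store.get_treatment(treatment_id)
        share = treatment.share_as_of(as_of_date) or PatientShare.some
        circles.append(
            PlotCircle(
                treatment_id=treatment_id,
                square=square,
                modality_colour=MODALITY_COLOURS[treatment.modality],
                shade_tier=strength_tier(cumulative[(treatment_id, square)], cfg),
                size_class=_SIZE_FOR_SHARE[share],
                cumulative_weight=cumulative[(treatment_id, square)],
                as_of_date=as_of_date,
            )
        )
    return circles, list(paths)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, already loaded."""

    store: EvidenceStore
    hierarchy: EvidenceHierarchy
    layout: MatrixLayout
    matrices: list[ValueMatrix]
    custom: CustomWeights
    scoring: ScoringConfig
    query: Query = field(default_factory=Query)
    end_year: Optional[int] = None
    as_of_date: Optional[datetime.date] = None
    paths: list[TreatmentGoalPath] = field(default_factory=list)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the five stages — capture, pieces, review/assign, raw
    scores, value weighting — and write series.csv, plot_data.json,
    stats.json and run.log, each stamped with the config fingerprint.

    Any stage failure removes partial outputs and raises a stage-named
    error; two runs on the same inputs produce identical artifacts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []
    fingerprint = config_fingerprint(
        config.hierarchy, config.matrices, config.custom, config.layout, config.scoring
    )

    def fail(stage: str, exc: Exception):
        for path in written:
            if path.exists():
                path.unlink()
        raise StageError(stage, str(exc)) from exc

    # stage 1-2: capture + pieces (the store already holds disaggregated rows)
    try:
        config.store.validate()
        dates = [
            config.store.piece_date(p) for p in config.store.pieces.values()
        ]
        log_lines.append(
            f"capture: {len(config.store.references)} references, "
            f"{len(config.store.treatments)} treatments, "
            f"{len(config.store.pieces)} pieces"
        )
    except Exception as exc:  # noqa: BLE001
        fail("capture", exc)

    end_year = config.end_year or (max(d.year for d in dates) if dates else 1970)
    as_of = config.as_of_date or (max(dates) if dates else datetime.date(1970, 1, 1))

    # stage 3: review/assign — qualification census
    try:
        n_qualifying = sum(
            1
            for p in config.store.query_pieces(config.query)
            if qualifies(p, config.scoring)
        )
        log_lines.append(f"review: {n_qualifying} qualifying pieces for query")
    except Exception as exc:  # noqa: BLE001
        fail("review", exc)

    # stage 4-5: raw scores + value weighting
    try:
        series = compute_escore_series(
            config.query,
            config.store,
            config.hierarchy,
            config.matrices,
            config.custom,
            config.layout,
            config.scoring,
            end_year,
        )
        series_path = out_dir / "series.csv"
        with open(series_path, "w") as fh:
            fh.write(f"# fingerprint={fingerprint}\n")
            fh.write("year,score,n_pieces_counted\n")
            for row in series.as_rows():
                fh.write(
                    f"{row['year']},{row['score']:.9g},{row['n_pieces_counted']}\n"
                )
        written.append(series_path)
        log_lines.append(f"score: final E-Score {series.final():.6g} at {end_year}")
    except Exception as exc:  # noqa: BLE001
        fail("score", exc)

    try:
        circles, paths = matrix_plot_data(
            config.query,
            as_of,
            config.store,
            config.hierarchy,
            config.layout,
            config.scoring,
            config.paths,
        )
        plot_path = out_dir / "plot_data.json"
        plot_payload = {
            "fingerprint": fingerprint,
            "as_of_date": as_of.isoformat(),
            "circles": [c.model_dump(mode="json") for c in circles],
            "paths": [p.model_dump(mode="json") for p in paths],
        }
        plot_path.write_text(json.dumps(plot_payload, indent=2, sort_keys=True))
        written.append(plot_path)
        log_lines.append(f"plot: {len(circles)} circles")
    except Exception as exc:  # noqa: BLE001
        fail("plot", exc)

    try:
        stats = reversal_stats(
            config.store, config.layout, require_release=False
        )
        stats_path = out_dir / "stats.json"
        stats_payload = {"fingerprint": fingerprint, **stats}
        stats_path.write_text(json.dumps(stats_payload, indent=2, sort_keys=True))
        written.append(stats_path)
        log_lines.append(
            f"stats: {stats['totals']['n_override_events']} override events"
        )
    except Exception as exc:  # noqa: BLE001
        fail("stats", exc)

    log_path = out_dir / "run.log"
    log_path.write_text(
        "\n".join([f"fingerprint={fingerprint}", *log_lines]) + "\n"
    )
    written.append(log_path)
    return {
        "fingerprint": fingerprint,
        "series": series,
        "circles": circles,
        "stats": stats,
        "artifacts": [str(p) for p in written],
    }
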
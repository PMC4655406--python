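"""End-to-end pipeline: image(s) in → neurons, tables, SWC out.

Also hosts the threshold-sweep precision/recall evaluation used to compare
soma-only detection against detection validated by neurite tracing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import ImageGrid, ImageStack, ScaleInfo, load_image, load_stack, write_swc
from .neurite_tracing import (
    TraceParams,
    find_initial_points,
    trace_fcm,
    trace_hmm,
    trace_stack,
)
from .quantify import (
    QuantParams,
    assemble_neurons,
    match_detections,
    records_frame,
    total_length,
)
from .soma_detection import (
    SomaParams,
    default_nms_window_px,
    detect_somata,
    log_response,
    nms_centers,
    refine_boundary,
    soma_regions,
)

__all__ = ["RunConfig", "run_pipeline", "trace_from_somata", "pr_curve"]

log = logging.getLogger("neurotrace")


@dataclass
class RunConfig:
    input_path: str
    microns_per_pixel: float = 0.3125
    microns_per_slice: float | None = None
    soma: SomaParams = field(default_factory=SomaParams)
    trace: TraceParams = field(default_factory=TraceParams)
    quant: QuantParams = field(default_factory=QuantParams)
    model: str = "fcm"  # "hmm" | "fcm"
    mode: str = "2d"  # "2d" | "stack"
    output_dir: str = "."
    fallback_seeding: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("hmm", "fcm"):
            raise ValueError("model must be 'hmm' or 'fcm'")
        if self.mode not in ("2d", "stack"):
            raise ValueError("mode must be '2d' or 'stack'")

    @property
    def scale(self) -> ScaleInfo:
        return ScaleInfo(self.microns_per_pixel, self.microns_per_slice)


def _tracer(model: str):
    return trace_hmm if model == "hmm" else trace_fcm


def trace_from_somata(image: ImageGrid, somata, tparams: TraceParams, model="fcm"):
    """Trace every initial point on every soma's 40-μm circle; sequences are
    tagged with their soma of origin."""
    tracer = _tracer(model)
    sequences = []
    for sid, soma in enumerate(somata):
        for ip in find_initial_points(image, soma.center, tparams):
            seq = tracer(image, ip, tparams, soma_center=soma.center)
            seq.soma_id = sid
            sequences.append(seq)
    return sequences


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write CSV/SWC/report into output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scale = config.scale

    if config.mode == "stack":
        stack = load_stack(config.input_path, scale)
        sequences = trace_stack(stack, None, config.trace)
        neurons = []
        somata = []
    else:
        image = load_image(config.input_path, scale)
        somata = detect_somata(image, config.soma)
        sequences = trace_from_somata(image, somata, config.trace, config.model)
        if not somata and config.fallback_seeding:
            log.info("no somata found; falling back to neurite-like seeding")
            stack = ImageStack(slices=[image])
            sequences = trace_stack(stack, None, config.trace)
        neurons = assemble_neurons(somata, sequences, config.quant, scale)

    frame = records_frame(neurons)
    frame.to_csv(out / "neurites.csv", index=False)
    retained = [r.sequence for n in neurons for r in n.neurites]
    swc_sequences = retained if neurons else [s for s in sequences if len(s.points) >= 2]
    write_swc(swc_sequences, [n.soma for n in neurons], out / "morphology.swc", scale)
    _write_points_csv(swc_sequences, out / "trace_points.csv")

    report = {
        "input": str(config.input_path),
        "mode": config.mode,
        "model": config.model,
        "n_somata_detected": len(somata),
        "n_neurons": len(neurons),
        "n_sequences_traced": len(sequences),
        "n_neurites_retained": int(len(frame)),
        "total_neurite_length_um": float(frame["length_um"].sum()) if len(frame) else 0.0,
        "seed": config.trace.seed,
        "params": {
            "soma": asdict(config.soma),
            "trace": asdict(config.trace),
            "quant": asdict(config.quant),
            "microns_per_pixel": config.microns_per_pixel,
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _write_points_csv(sequences, path):
    rows = []
    for k, seq in enumerate(sequences):
        for pt in seq.points:
            pos = list(np.asarray(pt.position, float))
            rows.append(
                {
                    "sequence": k,
                    "step_index": pt.step_index,
                    "row": pos[0],
                    "col": pos[1],
                    "depth": pos[2] if len(pos) == 3 else 0.0,
                    "score": seq.log_posterior,
                }
            )
    pd.DataFrame(
        rows, columns=["sequence", "step_index", "row", "col", "depth", "score"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Precision/recall sweep (soma-only vs soma+neurite)


def pr_curve(
    phantoms,
    thresholds,
    sparams: SomaParams | None = None,
    tparams: TraceParams | None = None,
    qparams: QuantParams | None = None,
    model: str = "fcm",
) -> pd.DataFrame:
    """Precision/recall of soma detection across a response-ratio-threshold
    sweep, pooled over phantoms, for the soma-only detector and for the
    detector validated by neurite tracing (somata without a ≥20-μm traced
    neurite are rejected).

    Candidate sets are nested in the threshold, so detection and tracing run
    once per phantom at the lowest threshold and the sweep reuses them.
    """
    sparams = sparams or SomaParams()
    tparams = tparams or TraceParams()
    qparams = qparams or QuantParams()
    thresholds = sorted(thresholds)
    tracer = _tracer(model)

    per_phantom = []
    for ph in phantoms:
        image = ph.image
        base = SomaParams(**{**asdict(sparams), "response_ratio_threshold": thresholds[0]})
        resp = log_response(image, base)
        mask = soma_regions(resp, base)
        cands = nms_centers(resp, mask, default_nms_window_px(image))
        infos = []
        for cand in cands:
            soma = refine_boundary(image, cand, base)
            has_neurite = False
            import warnings as _warnings

            for ip in find_initial_points(image, cand.center, tparams):
                seq = tracer(image, ip, tparams, soma_center=cand.center)
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    L = total_length(seq, soma, image.scale)
                if L >= qparams.min_neurite_len_um:
                    has_neurite = True
                    break
            infos.append(
                {
                    "center": cand.center,
                    "ratio": cand.response_ratio,
                    "has_neurite": has_neurite,
                }
            )
        per_phantom.append((infos, [tuple(c) for c in ph.true_soma_centers], image.scale))

    rows = []
    for thr in thresholds:
        pooled = {"det": 0, "mat": 0, "detc": 0, "matc": 0, "true": 0}
        for infos, truth, scale in per_phantom:
            radius_px = qparams.match_radius_um / scale.microns_per_pixel
            det = [i for i in infos if i["ratio"] >= thr]
            detc = [i for i in det if i["has_neurite"]]
            pooled["det"] += len(det)
            pooled["detc"] += len(detc)
            pooled["true"] += len(truth)
            pooled["mat"] += match_detections([i["center"] for i in det], truth, radius_px)
            pooled["matc"] += match_detections(
                [i["center"] for i in detc], truth, radius_px
            )
        rows.append(
            {
                "threshold": thr,
                "n_detected": pooled["det"],
                "precision_soma": 1.0 if pooled["det"] == 0 else pooled["mat"] / pooled["det"],
                "recall_soma": 0.0 if pooled["true"] == 0 else pooled["mat"] / pooled["true"],
                "n_detected_combined": pooled["detc"],
                "precision_combined": 1.0
                if pooled["detc"] == 0
                else pooled["matc"] / pooled["detc"],
                "recall_combined": 0.0
                if pooled["true"] == 0
                else pooled["matc"] / pooled["true"],
            }
        )
    return pd.DataFrame(rows)
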
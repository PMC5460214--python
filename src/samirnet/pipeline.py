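"""End-to-end pipeline driver: config in, materialised stage outputs out.

Thin orchestration over `SenescenceTargetModel`: reads every input named in
the config, runs the stages in order, writes the per-stage tables, the
GraphML sub-network export and a deterministic JSON report (input hashes
and applied settings included, no timestamps). A failure in any stage
aborts with an error naming the stage.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import io as sio
from .model import SenescenceTargetModel, input_hashes

log = logging.getLogger("samirnet")

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: dict | str | Path, outdir, rng_seed: int = 0) -> dict:
    """Run the full analysis described by a config mapping or YAML path.

    Returns the report dict; all artifacts are written under ``outdir``.
    """
    if not isinstance(config, dict):
        config = sio.load_config(config)
    outdir = Path(outdir)

    try:
        model = SenescenceTargetModel.from_files(config)
    except (sio.ConfigError, sio.DataValidationError):
        raise
    except Exception as e:  # unexpected read failure still names the stage
        raise PipelineError("load_inputs", e) from e

    log.info(
        "thresholds: fc_min=%g drpkm_min=%g pseudocount=%g score<%g alpha=%g n_sim=%d seed=%d",
        model.thresholds.fc_min, model.thresholds.drpkm_min,
        model.thresholds.pseudocount, model.score_threshold, model.alpha,
        model.n_sim, rng_seed,
    )
    try:
        results = model.fit(rng_seed=rng_seed)
    except sio.DataValidationError:
        raise
    except Exception as e:
        raise PipelineError("fit", e) from e

    try:
        results.save(outdir)
        report = results.report()
        report["inputs"] = input_hashes(config)
        sio.write_report(report, outdir / "report.json")
    except Exception as e:
        raise PipelineError("write_outputs", e) from e
    return report
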
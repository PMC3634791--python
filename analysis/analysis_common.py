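"""Shared plumbing for the numbered analysis drivers.

Each driver works off one pipeline run of the synthetic three-population
study.  The heavyweight run directory (genotype VCFs and full scan
tables) lives under scratch/; the drivers distill small narrative tables
into results/analysis/.
"""

from __future__ import annotations

import json
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "analysis_run"
OUT_DIR = ROOT / "results" / "analysis"
SEED = 1


def ensure_run() -> dict:
    """Run the pipeline once (cached in scratch/) and return its report."""
    report_path = RUN_DIR / "report.json"
    if not report_path.exists():
        from vertfine.config import RunConfig
        from vertfine.pipeline import render_reports, run_pipeline

        cfg = RunConfig(seed=SEED, out_dir=str(RUN_DIR))
        run_pipeline(cfg)
        render_reports(RUN_DIR, make_plot=True)
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    return json.loads(report_path.read_text())
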
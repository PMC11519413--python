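"""End-to-end orchestration: simulate -> derive -> sensitivity -> dependence
-> adequacy, with every intermediate materialized as CSV, stage-level
logging, and a manifest that makes a run's determinism checkable (seed,
config hash, per-stage row counts and file hashes)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import adequacy as adequacy_mod
from . import dependence as dependence_mod
from . import derive as derive_mod
from . import sensitivity as sensitivity_mod
from . import simulate as simulate_mod
from .errors import PipelineError

logger = logging.getLogger(__name__)

STAGES = ["simulate", "derive", "sensitivity", "dependence", "adequacy"]

_FILES = {
    "simulate": "cohort.csv",
    "derive": "derived.csv",
    "sensitivity": "sensitivity.csv",
    "dependence": "dependence.csv",
    "adequacy": "adequacy.txt",
}


@dataclass
class RunConfig:
    """One reproducible run of the full analysis."""

    outdir: str | Path = "nephrometry_run"
    seed: int = 0
    sim: simulate_mod.SimConfig | None = None
    adequacy: adequacy_mod.AdequacyConfig | None = None
    pairs_file: str | Path | None = None  # None -> shipped default battery
    q: float = dependence_mod.DEFAULT_FDR_Q
    method: str = "permutation"
    n_perm: int = dependence_mod.DEFAULT_N_PERM
    density_q: float = 0.10
    sensitivity_unit: str = "slide"
    variables: list[str] | None = None

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = simulate_mod.SimConfig(seed=self.seed)
        if self.adequacy is None:
            self.adequacy = adequacy_mod.AdequacyConfig()

    def config_hash(self) -> str:
        def _default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            raise TypeError(type(o))

        # output location does not affect what is computed
        fields = {k: v for k, v in dataclasses.asdict(self).items() if k != "outdir"}
        payload = json.dumps(fields, sort_keys=True, default=_default)
        return hashlib.sha256(payload.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; abort naming the failing stage.

    Partial outputs of completed stages are retained on failure.  Returns
    the manifest (also written to ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    stage = "simulate"
    try:
        cohort = simulate_mod.simulate_cohort(config.sim)
        path = outdir / _FILES[stage]
        simulate_mod.write_cohort(cohort, path)
        n_biopsies = cohort["biopsy_id"].nunique()
        n_slides = int((~cohort["excluded"]).sum())
        n_medulla = int(cohort.loc[~cohort["excluded"], "medulla_present"].sum())
        manifest["stages"][stage] = {
            "rows": len(cohort),
            "biopsies": int(n_biopsies),
            "slides": n_slides,
            "excluded_biopsies": int(cohort["excluded"].sum()),
            "medulla_slides": n_medulla,
            "sha256": _sha256(path),
        }
        logger.info("simulate: %d biopsies, %d slides (%d medulla-bearing)",
                    n_biopsies, n_slides, n_medulla)

        stage = "derive"
        derived = derive_mod.derive_variables(cohort)
        path = outdir / _FILES[stage]
        derive_mod.write_derived(derived, path)
        missing_intensive = int(derived["glomeruli_per_area"].isna().sum())
        manifest["stages"][stage] = {
            "rows": len(derived),
            "missing_intensive": missing_intensive,
            "sha256": _sha256(path),
        }
        logger.info("derive: %d slides, %d with missing intensive variables",
                    len(derived), missing_intensive)

        stage = "sensitivity"
        sens = sensitivity_mod.sensitivity_table(
            derived, variables=config.variables, unit=config.sensitivity_unit
        )
        path = outdir / _FILES[stage]
        sensitivity_mod.write_sensitivity(sens, path)
        manifest["stages"][stage] = {"rows": len(sens), "sha256": _sha256(path)}

        stage = "dependence"
        pairs = None
        if config.pairs_file is not None:
            pairs = dependence_mod.load_pairs_config(Path(config.pairs_file).read_text())
        dep = dependence_mod.run_dependence_battery(
            derived, pairs=pairs, q=config.q, method=config.method,
            n_perm=config.n_perm, seed=config.seed,
        )
        path = outdir / _FILES[stage]
        dependence_mod.write_dependence(dep, path)
        manifest["stages"][stage] = {
            "rows": len(dep),
            "tests": len(dep),
            "rejected": int(dep["rejected"].sum()),
            "sha256": _sha256(path),
        }

        stage = "adequacy"
        result, flags = adequacy_mod.adequacy_report(
            derived, config.adequacy, density_q=config.density_q
        )
        path = outdir / _FILES[stage]
        path.write_text(adequacy_mod.format_report(result, flags) + "\n")
        flags.to_csv(outdir / "adequacy_flags.csv", index=False)
        manifest["stages"][stage] = {
            "rows": len(flags),
            "n_star": result.n_star,
            "adequate_slides": int(flags["adequate"].sum()),
            "recommended_area": result.recommended_area_rounded,
            "sha256": _sha256(path),
        }
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    report = make_report({s: outdir / _FILES[s] for s in STAGES})
    (outdir / "report.txt").write_text(report)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def make_report(stage_outputs: dict) -> str:
    """Consolidated plain-text report from materialized stage outputs.

    ``stage_outputs`` maps stage name to file path.  Stages not in the
    mapping are marked absent; a mapped path that does not exist is an
    error naming the stage.
    """
    for stage, path in stage_outputs.items():
        if not Path(path).exists():
            raise PipelineError(f"missing output for stage {stage!r}: {path}")

    sections = ["# Nephrometry analysis report", ""]

    sections.append("## Variable dictionary")
    if "derive" in stage_outputs:
        derived = pd.read_csv(stage_outputs["derive"], nrows=1)
        base = [c for c in derived.columns if c not in derive_mod.DERIVED_FIELDS]
        sections.append("measured per slide: " + ", ".join(base))
        sections.append("derived per slide: " + ", ".join(derive_mod.DERIVED_FIELDS))
    else:
        sections.append("(absent)")
    sections.append("")

    sections.append("## Sensitivity: % variance explained by inter-donor differences")
    if "sensitivity" in stage_outputs:
        sens = pd.read_csv(stage_outputs["sensitivity"])
        for _, r in sens.iterrows():
            tag = " [PAS only]" if r["restricted_to_pas"] else ""
            sections.append(
                f"  {r['variable']:<24s} inter {r['pct_inter_donor']:6.2f}%  "
                f"intra {r['pct_intra_donor']:6.2f}%  (n={int(r['n_used'])}){tag}"
            )
    else:
        sections.append("(absent)")
    sections.append("")

    sections.append("## Processing dependencies (BH-rejected pairs)")
    if "dependence" in stage_outputs:
        dep = pd.read_csv(stage_outputs["dependence"])
        rejected = dep[dep["rejected"]]
        sections.append(f"{len(dep)} tests, {len(rejected)} rejected")
        for _, r in rejected.iterrows():
            sections.append(
                f"  {r['processing_variable']} -> {r['morphometric_variable']}"
                f" ({r['test']}, p={r['p_value']:.4g})"
            )
    else:
        sections.append("(absent)")
    sections.append("")

    sections.append("## Glomerular adequacy")
    if "adequacy" in stage_outputs:
        sections.append(Path(stage_outputs["adequacy"]).read_text().rstrip())
    else:
        sections.append("(absent)")
    sections.append("")
    return "\n".join(sections)
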
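"""Run orchestration: load inputs, run analyses, write artifacts.

Every run logs the SHA-256 digest of the configuration text (and the seed
where randomness is involved), so any artifact can be reproduced from the
log line alone.  Artifacts go into a run directory with a ``manifest.json``
listing every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .cea import CEAComparison, compute_icer
from .model import StrategyOutcome, run_cohort
from .parameters import (
    LifeTable,
    ParameterSet,
    from_config_text,
    validate_parameters,
)
from .fixtures import default_life_table

__all__ = ["ConfigValidationError", "RunReport", "run_base_case"]

log = logging.getLogger("gistcea")


class ConfigValidationError(ValueError):
    """Raised when a configuration violates parameter invariants."""

    def __init__(self, violations: list[str]):
        super().__init__("invalid configuration:\n  " + "\n  ".join(violations))
        self.violations = violations


def config_digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def load_inputs(config_path, life_table_path=None) -> tuple[ParameterSet, LifeTable, str]:
    """Read and validate the configuration and life table.

    ``life_table_path=None`` falls back to the synthetic default table.
    Raises :class:`ConfigValidationError` on invariant violations and
    ``FileNotFoundError`` before any output is produced.
    """
    text = Path(config_path).read_text()
    params = from_config_text(text)
    violations = validate_parameters(params)
    if violations:
        raise ConfigValidationError(violations)
    if life_table_path is None:
        life_table = default_life_table()
    else:
        life_table = LifeTable.from_csv(life_table_path)
    return params, life_table, config_digest(text)


@dataclass
class RunReport:
    """Record of one orchestrated run."""

    config_digest: str
    outcomes: dict[str, StrategyOutcome]
    comparison: CEAComparison
    artifacts: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (f"config {self.config_digest}\n" + self.comparison.summary())


def run_base_case(config_path, life_table_path=None,
                  outdir=None) -> RunReport:
    """Run both strategies on a configuration and export the comparison.

    Writes ``comparison.csv``, ``comparison.json``, per-strategy trace CSVs
    and a manifest when ``outdir`` is given.
    """
    params, life_table, digest = load_inputs(config_path, life_table_path)
    log.info("base case: config digest %s", digest)
    outcomes = {s: run_cohort(s, params, life_table) for s in ("UAPR", "CIUP")}
    comparison = compute_icer(outcomes["UAPR"], outcomes["CIUP"], wtp=params.wtp)
    report = RunReport(digest, outcomes, comparison)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        comparison.to_frame().to_csv(out / "comparison.csv", index=False)
        (out / "comparison.json").write_text(comparison.to_json())
        report.artifacts += ["comparison.csv", "comparison.json"]
        for name, o in outcomes.items():
            fname = f"trace_{name}.csv"
            o.trace.to_frame(o.space).to_csv(out / fname, index=False)
            report.artifacts.append(fname)
        write_manifest(out, report.artifacts, digest)
        report.artifacts.append("manifest.json")
    return report


def write_manifest(outdir: Path, artifacts: list[str], digest: str,
                   seed: int | None = None) -> None:
    manifest = {"config_digest": digest, "artifacts": sorted(artifacts)}
    if seed is not None:
        manifest["seed"] = seed
    (Path(outdir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
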
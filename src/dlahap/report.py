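"""Structured run reports: per-stage record counts, results, warnings."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

from . import __version__
from .association import AssociationResult


@dataclass
class RunReport:
    tool_version: str = __version__
    command: str = ""
    input_digests: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    results: list[dict[str, Any]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    error: Optional[str] = None

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        self.input_digests[p.name] = digest

    def add_association(self, res: AssociationResult, n_tested: int = 1) -> None:
        t = res.table
        self.results.append({
            "exposure": res.exposure,
            "comparison": res.comparison,
            "unit": t.unit,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "odds_ratio": round(res.odds_ratio, 4),
            "ci_low": round(res.ci_low, 4),
            "ci_high": round(res.ci_high, 4),
            "chi2_yates": round(res.chi2_yates, 4),
            # two significant figures in reports; full precision kept upstream
            "p_value": float(f"{res.p_value:.2g}"),
            "n_tested": n_tested,
        })

    def reconcile(self, loaded: int, analysed: int, excluded: int) -> None:
        if loaded != analysed + excluded:
            self.warnings.append(
                f"count mismatch: loaded={loaded} != analysed={analysed} + excluded={excluded}"
            )
        self.counts.update(loaded=loaded, analysed=analysed, excluded=excluded)

    def write(self, path: str | Path) -> None:
        payload = {
            "tool_version": self.tool_version,
            "command": self.command,
            "input_digests": self.input_digests,
            "counts": self.counts,
            "results": self.results,
            "warnings": self.warnings,
            "error": self.error,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
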
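"""Study report: per-species calibrations, summary table, correlations.

The report mirrors the standard presentation of a multi-species calibration
study: a summary table of M_w, L_A, LDM and SLA as mean +/- SD with Tukey
compact letters; a correlation table of adjusted R^2 for tau vs M_w, tau vs
L_A and tau*L_A vs M_w with significance stars; and the fitted calibration
line per species. Machine-readable JSON is the primary artifact; rendered
text tables and figures are derived from the same numbers, formatted to two
decimals. Reports are deterministic: identical inputs yield byte-identical
JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibrate import CalibrationModel, correlation_table, tukey_letters
from .core import LeafRecord
from .errors import ReportError
from .io import RunConfig

__all__ = ["StudyReport", "build_report"]

_SUMMARY_VARS = {
    "Mw_mg": lambda r: r.water_mass,
    "LA_cm2": lambda r: r.leaf_area,
    "LDM_mg": lambda r: r.dry_mass,
    "SLA_cm2_per_mg": lambda r: r.sla,
}


@dataclass
class StudyReport:
    """Assembled report; ``data`` is the canonical JSON-able payload."""

    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True) + "\n"

    def save(self, path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    def render_text(self) -> str:
        """Human-readable tables (2-decimal formatting) from the JSON payload."""
        lines = []
        summary = self.data["summary"]
        species = self.data["species_order"]
        lines.append("Per-species summary (mean ± SD; shared letters: not significantly different)")
        header = f"{'variable':>16}" + "".join(f"{s:>22}" for s in species)
        lines.append(header)
        for var in _SUMMARY_VARS:
            cells = []
            for s in species:
                cell = summary[var][s]
                txt = f"{cell['mean']:.2f} ± {cell['sd']:.2f}"
                if cell.get("letters"):
                    txt += f" {cell['letters']}"
                cells.append(f"{txt:>22}")
            lines.append(f"{var:>16}" + "".join(cells))
        if self.data.get("tukey_note"):
            lines.append(f"  note: {self.data['tukey_note']}")
        lines.append("")
        lines.append("Adjusted R² of the candidate regressions (* : Pearson p ≤ α)")
        lines.append(f"{'relation':>16}" + "".join(f"{s:>12}" for s in species))
        for rel in ("tau_vs_Mw", "tau_vs_LA", "tauLA_vs_Mw"):
            cells = []
            for s in species:
                cell = self.data["correlations"][s][rel]
                star = " *" if cell["significant"] else "  "
                cells.append(f"{cell['adj_r2']:>10.2f}{star}")
            lines.append(f"{rel:>16}" + "".join(cells))
        lines.append("")
        lines.append("Calibration fits: tau·L_A = C1·M_w + C0")
        lines.append(
            f"{'species':>10}{'C1':>10}{'±SE':>10}{'C0':>12}{'adj_R2':>10}{'n':>6}"
        )
        for s in species:
            m = self.data["calibrations"].get(s)
            if m is None:
                continue
            lines.append(
                f"{s:>10}{m['C1']:>10.2f}{m['se_C1']:>10.2f}"
                f"{m['C0']:>12.2f}{m['adj_r2']:>10.2f}{m['n']:>6d}"
            )
        return "\n".join(lines) + "\n"

    def save_figures(self, out_dir) -> list[str]:
        """One tau·L_A vs M_w scatter with its fitted line per species."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for s in self.data["species_order"]:
            pts = self.data["points"].get(s)
            m = self.data["calibrations"].get(s)
            if not pts or m is None:
                continue
            x = np.asarray(pts["M_w_mg"])
            y = np.asarray(pts["tauLA_cm2"])
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.scatter(x, y, color="k", s=18, zorder=3)
            xx = np.linspace(0, float(x.max()) * 1.05, 50)
            ax.plot(xx, m["C1"] * xx + m["C0"], color="crimson", lw=1.5)
            ax.set_xlabel("$M_w$ (mg)")
            ax.set_ylabel(r"$\tau L_A$ (cm$^2$)")
            ax.set_title(f"{s}: $C_1$={m['C1']:.2f} cm$^2$ mg$^{{-1}}$, adj $R^2$={m['adj_r2']:.2f}")
            fig.tight_layout()
            p = out_dir / f"calibration_{s}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths.append(str(p))
        return paths


def build_report(
    records: Sequence[LeafRecord],
    models: Mapping[str, CalibrationModel],
    config: RunConfig = RunConfig(),
) -> StudyReport:
    """Assemble the full study report from records and fitted models."""
    if not models:
        raise ReportError("no fitted models; nothing to report")
    by_species: dict[str, list[LeafRecord]] = {}
    for r in records:
        by_species.setdefault(r.species_code, []).append(r)
    species_order = sorted(by_species)

    summary: dict[str, dict] = {}
    tukey_note = None
    for var, getter in _SUMMARY_VARS.items():
        groups = {s: [getter(r) for r in by_species[s]] for s in species_order}
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            letters = tukey_letters(groups, alpha=config.alpha_level)
        else:
            letters = {s: "" for s in groups}
            tukey_note = "Tukey letters omitted: need >= 2 species with >= 2 leaves each"
        summary[var] = {
            s: {
                "mean": float(np.mean(groups[s])),
                "sd": float(np.std(groups[s], ddof=1)) if len(groups[s]) > 1 else 0.0,
                "n": len(groups[s]),
                "letters": letters[s],
            }
            for s in species_order
        }

    corr = correlation_table(records, alpha=config.alpha_level)
    correlations = {
        s: {
            row["relation"]: {
                "adj_r2": float(row["adj_r2"]),
                "pearson_p": float(row["pearson_p"]),
                "significant": bool(row["significant"]),
            }
            for _, row in corr[corr["species"] == s].iterrows()
        }
        for s in species_order
    }

    calibrations = {}
    points = {}
    for s, m in models.items():
        calibrations[s] = {
            "C1": m.C1, "se_C1": m.se_C1, "C0": m.C0, "se_C0": m.se_C0,
            "r2": m.r2, "adj_r2": m.adj_r2, "pearson_r": m.pearson_r,
            "pearson_p": m.pearson_p, "n": m.n, "residual_sd": m.residual_sd,
        }
    for s in species_order:
        points[s] = {
            "M_w_mg": [r.water_mass for r in by_species[s]],
            "tauLA_cm2": [r.tau_la for r in by_species[s]],
        }

    data = {
        "alpha_level": config.alpha_level,
        "confidence": config.confidence,
        "species_order": species_order,
        "summary": summary,
        "correlations": correlations,
        "calibrations": calibrations,
        "points": points,
    }
    if tukey_note:
        data["tukey_note"] = tukey_note
    return StudyReport(data=data)
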
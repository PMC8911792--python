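"""Optimal extraction conditions and the summary optimization report.

"Optimization" here is argmax over the measured factorial conditions — the
procedure actually available for a 5 × 3 designed experiment — plus
fold-changes between user-chosen condition pairs.  An optional refinement
step densely samples each response's fitted spline curve and reports the
curve maximum alongside the grid maximum; because the parametric curve
interpolates the grid rather than modeling a response surface, the refined
value is exploratory and can only meet or exceed the grid optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .dataset import Condition, ExtractionDataset, extreme_condition, fold_change
from .spline import SplineCurveModel

__all__ = ["OptimizationReport", "optimize", "report", "DEFAULT_FOLD_PAIR"]

# the contrast most often reported: hottest vs coolest extraction at the peak
# ethanol fraction (65 °C, 60 %) vs (30 °C, 60 %)
DEFAULT_FOLD_PAIR = (Condition(65, 60), Condition(30, 60))


@dataclass
class OptimizationReport:
    optimum: dict[str, tuple[Condition, float]]  # response -> (condition, mean)
    minimum: dict[str, tuple[Condition, float]]
    fold_changes: dict[str, dict[str, float | list[float]]]
    consensus: Condition
    units: dict[str, str] = field(default_factory=dict)
    refined: dict[str, dict[str, float]] | None = None


def _consensus(ds: ExtractionDataset, optima: dict[str, tuple[Condition, float]]) -> Condition:
    counts: dict[Condition, int] = {}
    for cond, _ in optima.values():
        counts[cond] = counts.get(cond, 0) + 1
    best = max(counts.values())
    tied = [c for c, k in counts.items() if k == best]
    if len(tied) == 1:
        return tied[0]
    # tie-break: the tied condition with the higher TPC mean (falls back to
    # the first response if TPC is absent)
    ref = "TPC" if "TPC" in ds.responses else ds.response_names[0]
    return max(tied, key=lambda c: (ds.value(ref, c).mean, -c.temperature, -c.concentration))


def optimize(
    ds: ExtractionDataset,
    refine: bool = False,
    fold_pairs: list[tuple[Condition, Condition]] | None = None,
    decimals: int = 2,
    points_per_interval: int = 1000,
) -> OptimizationReport:
    """Build the optimization report for a factorial dataset.

    Parameters
    ----------
    refine
        Also fit a cubic spline curve per response and report the maximum of
        its response direction over a dense sampling (``points_per_interval``
        per knot interval).
    fold_pairs
        Condition pairs (numerator, denominator) for fold-changes; defaults
        to the (65 °C, 60 %) / (30 °C, 60 %) contrast when those conditions
        exist, else the per-dataset (max t, peak C) / (min t, peak C) pair.
    """
    optimum = {}
    minimum = {}
    for name in ds.response_names:
        c, v = extreme_condition(ds, name, "max")
        optimum[name] = (c, v.mean)
        c, v = extreme_condition(ds, name, "min")
        minimum[name] = (c, v.mean)

    if fold_pairs is None:
        if all(c in ds.conditions for c in DEFAULT_FOLD_PAIR):
            fold_pairs = [DEFAULT_FOLD_PAIR]
        else:
            fold_pairs = []

    fold_changes: dict[str, dict] = {}
    for num, den in fold_pairs:
        key = (
            f"({num.temperature:g},{num.concentration:g})/"
            f"({den.temperature:g},{den.concentration:g})"
        )
        fold_changes[key] = {
            name: fold_change(ds, name, num, den, decimals) for name in ds.response_names
        }

    refined = None
    if refine:
        refined = {}
        for name in ds.response_names:
            res = SplineCurveModel(ds, name).fit()
            samples = res.sample(points_per_interval)
            i = int(samples["response"].idxmax())
            refined[name] = {
                "s": float(samples["s"][i]),
                "t": float(samples["t"][i]),
                "C": float(samples["C"][i]),
                "response": float(samples["response"][i]),
            }

    return OptimizationReport(
        optimum=optimum,
        minimum=minimum,
        fold_changes=fold_changes,
        consensus=_consensus(ds, optimum),
        units=dict(ds.units),
        refined=refined,
    )


def _cond_json(c: Condition) -> dict:
    return {"temperature_C": c.temperature, "concentration_pct": c.concentration}


def report(rep: OptimizationReport, format: str = "json") -> str:
    """Serialize the report deterministically as JSON or Markdown."""
    if format == "json":
        payload = {
            "consensus_optimum": _cond_json(rep.consensus),
            "optimum": {
                k: {**_cond_json(c), "mean": m, "unit": rep.units.get(k, "")}
                for k, (c, m) in rep.optimum.items()
            },
            "minimum": {
                k: {**_cond_json(c), "mean": m, "unit": rep.units.get(k, "")}
                for k, (c, m) in rep.minimum.items()
            },
            "fold_changes": rep.fold_changes,
        }
        if rep.refined is not None:
            payload["curve_refined_optimum"] = rep.refined
        return json.dumps(payload, indent=2, sort_keys=True)
    if format == "markdown":
        lines = [
            "# Extraction optimization report",
            "",
            f"Consensus optimum: **{rep.consensus.temperature:g} °C, "
            f"{rep.consensus.concentration:g} % v/v**",
            "",
            "| response | unit | optimum (t, C) | max mean | minimum (t, C) | min mean |",
            "|---|---|---|---|---|---|",
        ]
        for name in rep.optimum:
            oc, om = rep.optimum[name]
            mc, mm = rep.minimum[name]
            flag = " ⭐" if oc == rep.consensus else ""
            lines.append(
                f"| {name} | {rep.units.get(name, '')} "
                f"| ({oc.temperature:g}, {oc.concentration:g}){flag} | {om:g} "
                f"| ({mc.temperature:g}, {mc.concentration:g}) | {mm:g} |"
            )
        for pair, ratios in rep.fold_changes.items():
            lines.append("")
            lines.append(f"Fold-changes {pair}: " + ", ".join(
                f"{k} ×{v:g}" for k, v in ratios.items()
            ))
        if rep.refined is not None:
            lines.append("")
            lines.append("Curve-refined maxima (exploratory, dense spline sampling):")
            for name, r in rep.refined.items():
                lines.append(
                    f"- {name}: {r['response']:.4f} at s = {r['s']:.3f} "
                    f"(t = {r['t']:.2f}, C = {r['C']:.2f})"
                )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")
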
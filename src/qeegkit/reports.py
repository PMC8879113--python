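"""JSON- and Markdown-ready report serialisation."""

from __future__ import annotations

from dataclasses import asdict

from .rules import RuleFinding, RuleReport
from .signature import CohortSummary, NeurofeedbackPlan, SignatureResult


def finding_to_dict(finding: RuleFinding) -> dict:
    return {
        "rule_id": finding.rule_id,
        "channel": finding.channel,
        "band": finding.band,
        "status": finding.status,
        "observed": list(finding.observed),
        "message": finding.message,
    }


def report_to_dict(report: RuleReport) -> dict:
    return {
        "patient_id": report.patient_id,
        "findings": [finding_to_dict(f) for f in report.findings],
        "n_violations": report.n_violations,
    }


def signature_to_dict(result: SignatureResult) -> dict:
    return {
        "patient_id": result.patient_id,
        "channels": {
            ch: {"low_smr": c.low_smr, "beta2_ge_alpha": c.beta2_ge_alpha}
            for ch, c in result.channels.items()
        },
        "tolerance_used": result.tolerance_used,
        "positive": result.positive,
    }


def cohort_to_dict(summary: CohortSummary) -> dict:
    return asdict(summary)


def plan_to_dict(plan: NeurofeedbackPlan) -> dict:
    return {
        "patient_id": plan.patient_id,
        "channel": plan.channel,
        "bands": {
            band: {
                "direction": bp.direction,
                "target_contribution_pct": bp.target_contribution_pct,
            }
            for band, bp in plan.bands.items()
        },
        "contributions_pct": plan.contributions_pct,
        "notes": plan.notes,
    }


def report_to_markdown(report: RuleReport) -> str:
    """Human-readable verdict list for one patient."""
    lines = [f"## Patient {report.patient_id}", ""]
    violations = report.violated()
    if violations:
        lines.append(f"{report.n_violations} rule violation(s):")
        lines.extend(f"- **{f.rule_id}** — {f.message}" for f in violations)
    else:
        lines.append("No rule violations.")
    infos = [f for f in report.findings if f.status == "info"]
    if infos:
        lines.append("")
        lines.append("Informational:")
        lines.extend(f"- {f.rule_id} — {f.message}" for f in infos)
    lines.append("")
    return "\n".join(lines)


def cohort_to_markdown(summary: CohortSummary) -> str:
    return "\n".join(
        [
            "## Cohort summary",
            "",
            f"- patients: {summary.n_patients}",
            f"- beta2 > alpha in both hemispheres: {summary.n_beta2_gt_alpha_both}",
            f"- theta > delta in both hemispheres: {summary.n_theta_gt_delta_both}",
            f"- alpha > theta in both hemispheres: {summary.n_alpha_gt_theta_both}",
            f"- >=1 band with supra-threshold C3/C4 asymmetry: {summary.n_asymmetry_flagged}",
            f"- signature-positive: {summary.n_signature_positive}",
            "",
        ]
    )
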
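"""End-to-end pipeline assembly and explanatory-table rendering.

``run_pipeline`` chains coding -> follow-up -> exclusions -> factor screening
-> nested models -> attenuation/bootstrap -> decomposition per sex, and
records a run manifest so every number in an output table traces back to
record counts, seeds and convergence flags.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, coding, followup
from .attenuation import (
    AttenuationResult,
    attenuation_from_fits,
    bootstrap_attenuation,
    decompose_from_attenuations,
    round_half_away,
)
from .hazard_models import (
    MODEL_SEQUENCE,
    FittedModel,
    fit_model_sequence,
    restrict_blocks,
    select_factors,
)
from .synthetic_cohort import SimulationConfig, generate_cohort

SEP_DISPLAY = {
    "1_low": "1-low",
    "2_mid_low": "2-middle low",
    "3_mid_high": "3-middle high",
    "4_high": "4-high",
}
NON_REF_SEP = ("1_low", "2_mid_low", "3_mid_high")


class RenderError(ValueError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    software_version: str = __version__
    input_fingerprint: str = ""
    counts: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    convergence: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)


def _fmt_hr(fit: FittedModel, level: str) -> str:
    sel = (fit.terms["covariate"] == "adulthood_sep") & (fit.terms["level"] == level)
    if not sel.any():
        return "-"
    row = fit.terms.loc[sel].iloc[0]
    return f"{row.hr:.2f} ({row.ci_low:.2f}-{row.ci_high:.2f})"


def _fmt_att(res: AttenuationResult | None) -> str:
    if res is None or not res.evaluable:
        return "-"
    pct = round_half_away(res.attenuation_pct)
    if pct >= 0:
        # no attenuation toward 1: shown as a dash, matching the convention
        # of printing percentages only where the excess hazard shrank
        return "-"
    if np.isfinite(res.ci_low_pct) and np.isfinite(res.ci_high_pct):
        return f"{pct}% ({round_half_away(res.ci_low_pct)} to {round_half_away(res.ci_high_pct)})"
    return f"{pct}%"


def render_explanatory_table(
    fits: dict[int, FittedModel],
    attenuations: dict[tuple[int, str], AttenuationResult],
    sex: str,
    group_sizes: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, str]:
    """Explanatory table: models 1-7 by SEP level, plus decomposition footer.

    Returns a tidy DataFrame (for CSV/JSON) and an aligned plain-text table.
    """
    missing = [m for m in range(1, 8) if m not in fits]
    if missing:
        raise RenderError(f"model sequence incomplete, missing models {missing}")

    rows = []
    for mid in range(1, 8):
        fit = fits[mid]
        row: dict[str, object] = {"model": f"Model {mid}"}
        for level in NON_REF_SEP:
            row[f"hr_{level}"] = _fmt_hr(fit, level)
            if mid == 1:
                row[f"att_{level}"] = ""
            else:
                row[f"att_{level}"] = _fmt_att(attenuations.get((mid, level)))
        row["hr_4_high"] = "1.00"
        rows.append(row)

    # decomposition footer per SEP level, from unrounded attenuations
    footer = {
        "direct_childhood": {"model": "Direct contribution of childhood conditions"},
        "direct_adulthood": {"model": "Direct contribution of adulthood risk factors"},
        "indirect_childhood": {"model": "Indirect contribution of childhood conditions"},
    }
    for level in NON_REF_SEP:
        atts = {}
        for mid in (2, 6, 7):
            res = attenuations.get((mid, level))
            atts[mid] = res.attenuation_pct if res is not None else float("nan")
        dec = decompose_from_attenuations(atts[2], atts[6], atts[7])
        footer["direct_childhood"][f"att_{level}"] = f"{round_half_away(dec.direct_childhood)}%"
        footer["direct_adulthood"][f"att_{level}"] = f"{round_half_away(dec.direct_adulthood)}%"
        footer["indirect_childhood"][f"att_{level}"] = (
            f"{round_half_away(dec.indirect_childhood)}%"
        )
    rows.extend(footer.values())

    table = pd.DataFrame(rows).fillna("")
    text = _plain_text(table, sex, group_sizes)
    return table, text


def _plain_text(table: pd.DataFrame, sex: str, group_sizes: dict[str, int] | None) -> str:
    head = f"Explanatory models, {sex}"
    if group_sizes:
        sizes = ", ".join(f"{SEP_DISPLAY[l]} n={group_sizes.get(l, '?')}" for l in SEP_DISPLAY)
        head += f" ({sizes})"
    cols = list(table.columns)
    widths = {c: max(len(str(c)), *(len(str(v)) for v in table[c])) for c in cols}
    lines = [head, ""]
    lines.append("  ".join(str(c).ljust(widths[c]) for c in cols))
    for _, row in table.iterrows():
        lines.append("  ".join(str(row[c]).ljust(widths[c]) for c in cols))
    return "\n".join(lines) + "\n"


def _hash_config(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    raw: pd.DataFrame | None = None,
    sim_config: SimulationConfig | None = None,
    seed: int = 0,
    boot: int = 1000,
    alpha: float = 0.05,
    ties: str = "breslow",
    screen: bool = True,
    out_dir: str | Path | None = None,
    sexes: tuple[str, ...] = ("male", "female"),
) -> tuple[dict[str, dict], RunManifest]:
    """Execute the full analysis per sex; optionally write results to disk.

    Either pass a raw cohort table or a simulation config (a default-config
    cohort is generated when both are None). ``boot = 0`` skips the bootstrap
    and flags the tables as CI-free.
    """
    if raw is None:
        sim_config = sim_config or SimulationConfig()
        raw = generate_cohort(sim_config, seed=seed)
        input_fp = f"synthetic:{_hash_config(asdict(sim_config))}:{seed}"
    else:
        input_fp = f"data:{_hash_config(raw.shape)}"

    manifest = RunManifest(
        config_hash=_hash_config(
            {"seed": seed, "boot": boot, "alpha": alpha, "ties": ties, "screen": screen}
        ),
        seed=seed,
        input_fingerprint=input_fp,
    )

    analytic, tally = followup.apply_exclusions(raw)
    manifest.exclusions = tally
    results: dict[str, dict] = {}

    for sex in sexes:
        sub = analytic[analytic["sex"] == sex].reset_index(drop=True)
        coded = coding.code_cohort(sub)
        surv = followup.derive_survival(sub)
        manifest.counts[sex] = {
            "analytic_n": int(len(sub)),
            "coded_n": int(len(coded)),
            "events": int(surv["event"].sum()),
        }

        blocks = None
        selection = None
        if screen:
            selection = select_factors(surv, coded, sex, alpha=alpha, ties=ties)
            blocks = restrict_blocks(selection)

        fits = fit_model_sequence(surv, coded, blocks=blocks, ties=ties)
        manifest.convergence[sex] = {mid: True for mid in fits}

        attenuations: dict[tuple[int, str], AttenuationResult] = {}
        for mid in range(2, 8):
            if boot > 0:
                spec_base = MODEL_SEQUENCE[1]
                spec_adj = MODEL_SEQUENCE[mid]
                if blocks is not None:
                    spec_base = _restricted(1, blocks)
                    spec_adj = _restricted(mid, blocks)
                boot_res = bootstrap_attenuation(
                    surv,
                    coded,
                    spec_base,
                    spec_adj,
                    B=boot,
                    seed=seed + mid,
                    sex=sex,
                    sep_levels=list(NON_REF_SEP),
                    ties=ties,
                )
                for level, res in boot_res.items():
                    attenuations[(mid, level)] = res
            else:
                point = attenuation_from_fits(
                    fits[1], fits[mid], list(NON_REF_SEP), sex=sex
                )
                for level, res in point.items():
                    res.flags.append("no_bootstrap")
                    attenuations[(mid, level)] = res
        if boot == 0:
            manifest.notes.append(f"{sex}: bootstrap skipped (boot=0), tables have no CIs")

        group_sizes = coded["adulthood_sep"].value_counts().to_dict()
        table, text = render_explanatory_table(fits, attenuations, sex, group_sizes)
        results[sex] = {
            "fits": fits,
            "attenuations": attenuations,
            "selection": selection,
            "table": table,
            "text": text,
            "group_sizes": group_sizes,
        }

    if out_dir is not None:
        _write_outputs(results, manifest, Path(out_dir))
    return results, manifest


def _restricted(mid: int, blocks) -> "ModelSpec":
    from .hazard_models import ModelSpec

    spec = MODEL_SEQUENCE[mid]
    covs = tuple(c for b in spec.blocks for c in blocks.get(b, coding.BLOCKS[b]))
    return ModelSpec(mid, spec.blocks, covariate_list=covs)


def _json_attenuations(attenuations: dict) -> list[dict]:
    out = []
    for (mid, level), res in sorted(attenuations.items()):
        out.append(
            {
                "model_id": mid,
                "sep_level": level,
                "hr_base": res.hr_base,
                "hr_adj": res.hr_adj,
                "attenuation_pct": None if not res.evaluable else res.attenuation_pct,
                "bca_ci": [res.ci_low_pct, res.ci_high_pct]
                if np.isfinite(res.ci_low_pct)
                else None,
                "flags": res.flags,
            }
        )
    return out


def _write_outputs(results: dict, manifest: RunManifest, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for sex, res in results.items():
        res["table"].to_csv(out_dir / f"explanatory_table_{sex}.csv", index=False)
        (out_dir / f"explanatory_table_{sex}.txt").write_text(res["text"])
        payload = {
            "attenuations": _json_attenuations(res["attenuations"]),
            "models": {
                mid: fit.terms.to_dict("records") for mid, fit in res["fits"].items()
            },
        }
        with open(out_dir / f"results_{sex}.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
        if res["selection"] is not None:
            res["selection"].evidence.to_csv(
                out_dir / f"factor_selection_{sex}.csv", index=False
            )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, default=str)
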
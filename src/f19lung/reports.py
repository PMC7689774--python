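"""Pipeline-level reports: theory reproduction, normalization tables, and a
fully seeded end-to-end simulated study.

``reproduce_theory`` evaluates the three fixed-scan-time predictions
(breath-hold, continuous breathing at the 70° Ernst angle, full recovery at
90°) from the shipped presets.  ``reproduce_table1_normalized`` redoes the
SNR/NSA normalization arithmetic on the study's reported values and flags
rows where the reported normalized value disagrees with the division.
``end_to_end_simulation`` runs simulate → measure → normalize → compare on
synthetic animals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import presets
from .image_snr import batch_compare
from .signal_model import predicted_advantage
from .stats_compare import ComparisonResult, compare_paired
from .synthetic import NoiseModel, PhantomSpec, default_rois, lung_mask, make_gre_image

__all__ = [
    "RunConfig",
    "THEORY_SCENARIOS",
    "reproduce_theory",
    "reproduce_table1_normalized",
    "end_to_end_simulation",
]

# (label, protocol_a, protocol_b, norm_nsa_a, norm_nsa_b).  The long
# continuous-70° scans are normalized by the breath-hold NSAs (16/24), the
# convention under which the published 98% figure was produced; breath-hold
# and full-recovery use their own NSAs.
THEORY_SCENARIOS: tuple[tuple[str, str, str, int | None, int | None], ...] = (
    ("breath-hold", "breath-hold-ofcb", "breath-hold-pfp", None, None),
    ("continuous-70", "continuous-70-ofcb", "continuous-70-pfp", 16, 24),
    ("full-recovery", "full-recovery-ofcb", "full-recovery-pfp", None, None),
)


def reproduce_theory(
    gas_a: str = "ofcb-invivo", gas_b: str = "pfp-invivo"
) -> pd.DataFrame:
    """Predicted NSA-normalized SNR advantages for the three protocols.

    Returns one row per scenario with the intermediate signals and a final
    ``mean`` row averaging the three advantages.
    """
    ga, gb = presets.gas(gas_a), presets.gas(gas_b)
    rows = []
    for label, pa_name, pb_name, norm_a, norm_b in THEORY_SCENARIOS:
        pa, pb = presets.protocol(pa_name), presets.protocol(pb_name)
        res = predicted_advantage(ga, gb, pa, pb, norm_nsa_a=norm_a, norm_nsa_b=norm_b)
        rows.append(
            {
                "scenario": label,
                "signal_a": res.signal_a,
                "signal_b": res.signal_b,
                "snr_theory_a": res.snr_theory_a,
                "snr_theory_b": res.snr_theory_b,
                "normalized_a": res.normalized_a,
                "normalized_b": res.normalized_b,
                "advantage_pct": res.advantage_pct,
            }
        )
    df = pd.DataFrame(rows)
    mean_row = {col: np.nan for col in df.columns}
    mean_row["scenario"] = "mean"
    mean_row["advantage_pct"] = df["advantage_pct"].mean()
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def reproduce_table1_normalized(atol: float = 0.005) -> pd.DataFrame:
    """Redo the SNR/NSA division on the study's reported in vivo values.

    Each row divides a reported SNR by its protocol NSA and compares with
    the reported normalized value; disagreements beyond rounding (``atol``
    on the 2-decimal scale) are flagged in ``discrepant`` and reported
    side by side, never silently replaced.
    """
    ref = presets.load_reference_snr()
    rows = []
    for entry in ref["in_vivo"]:
        computed = entry["snr"] / entry["nsa"]
        reported = entry.get("reported_normalized")
        discrepant = (
            reported is not None and abs(computed - reported) > atol + 1e-12
        )
        rows.append(
            {
                "gas": entry["gas"],
                "protocol": entry["protocol"],
                "source": entry.get("source", "summary-table"),
                "snr": entry["snr"],
                "nsa": entry["nsa"],
                "computed_normalized": computed,
                "reported_normalized": reported,
                "discrepant": discrepant,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Configuration of one simulated paired study."""

    gas_a: str = "ofcb-invivo"
    gas_b: str = "pfp-invivo"
    protocol_a: str = "breath-hold-ofcb"
    protocol_b: str = "breath-hold-pfp"
    n_animals: int = 5
    sigma_k: float = 3.07  # yields study-scale image SNR ~ 10 at breath-hold
    seed: int = 0
    snr_mode: str = "mean"
    concentration: float = 1.0
    outdir: str | None = None
    r_scale: float | None = None
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def end_to_end_simulation(config: RunConfig) -> dict[str, Any]:
    """Simulate a paired gas-comparison study and analyze it.

    For each simulated animal, one image per gas is generated from the same
    lung phantom geometry (independent noise), SNR is measured with the
    ROI-mean convention, normalized by NSA, and the paired samples are
    compared with the t test and JZS Bayes factor.  Fully deterministic for
    a fixed config (seeded RNG; one stream drives all noise draws).

    Returns a dict with the paired SNR table, the comparison result, the
    model-predicted advantage, and the measured mean normalized advantage.
    """
    ga, gb = presets.gas(config.gas_a), presets.gas(config.gas_b)
    pa, pb = presets.protocol(config.protocol_a), presets.protocol(config.protocol_b)
    if pa.matrix is None or pa.matrix != pb.matrix:
        raise ValueError("protocols must share a defined acquisition matrix")
    mask = lung_mask(pa.matrix)
    rois = default_rois(pa.matrix)
    rng = np.random.default_rng(config.seed)

    images_a, images_b = [], []
    for _ in range(config.n_animals):
        ph_a = PhantomSpec(mask=mask, fov_mm=pa.fov_mm or (100.0, 100.0),
                           gas=ga, concentration=config.concentration)
        ph_b = PhantomSpec(mask=mask, fov_mm=pb.fov_mm or (100.0, 100.0),
                           gas=gb, concentration=config.concentration)
        im_a, _ = make_gre_image(ph_a, pa, NoiseModel(sigma_k=config.sigma_k), seed=rng)
        im_b, _ = make_gre_image(ph_b, pb, NoiseModel(sigma_k=config.sigma_k), seed=rng)
        images_a.append(im_a)
        images_b.append(im_b)

    if config.sigma_k == 0:
        # noiseless limit: SNR is undefined, but the normalized comparison has
        # a well-defined limit shape signal·√NSA/NSA (unit k-space noise)
        rows = []
        for i, (im_a, im_b) in enumerate(zip(images_a, images_b)):
            sl = rois["signal"].slices
            snr_a = float(im_a.pixels[sl].mean()) * np.sqrt(pa.nsa)
            snr_b = float(im_b.pixels[sl].mean()) * np.sqrt(pb.nsa)
            rows.append(
                {
                    "id": f"subject{i+1}",
                    "snr_a": snr_a,
                    "snr_b": snr_b,
                    "normalized_a": snr_a / pa.nsa,
                    "normalized_b": snr_b / pb.nsa,
                }
            )
        table = pd.DataFrame(rows)
    else:
        table = batch_compare(
            images_a, images_b, rois["signal"], rois["noise"], mode=config.snr_mode
        )
    kwargs = {} if config.r_scale is None else {"r_scale": config.r_scale}
    comparison: ComparisonResult = compare_paired(
        table["normalized_a"], table["normalized_b"], **kwargs
    )
    predicted = predicted_advantage(ga, gb, pa, pb)
    measured_advantage = 100.0 * (
        table["normalized_a"].mean() / table["normalized_b"].mean() - 1.0
    )
    result = {
        "config": config,
        "table": table,
        "comparison": comparison,
        "predicted_advantage_pct": predicted.advantage_pct,
        "measured_advantage_pct": float(measured_advantage),
    }
    if config.outdir is not None:
        _write_outputs(result)
    return result


def _write_outputs(result: dict[str, Any]) -> None:
    config: RunConfig = result["config"]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = {"seed": config.seed, "config_hash": config.config_hash()}
    result["table"].assign(**tag).to_csv(outdir / "paired_snr.csv", index=False)
    summary = {
        **tag,
        "config": dataclasses.asdict(config),
        "comparison": dataclasses.asdict(result["comparison"]),
        "predicted_advantage_pct": result["predicted_advantage_pct"],
        "measured_advantage_pct": result["measured_advantage_pct"],
    }
    (outdir / "comparison.json").write_text(json.dumps(summary, indent=1))
    lines = [
        "# Simulated paired gas-comparison study",
        "",
        f"- seed: {config.seed}  (config hash {tag['config_hash']})",
        f"- animals: {config.n_animals}",
        f"- predicted advantage: {result['predicted_advantage_pct']:.1f}%",
        f"- measured advantage:  {result['measured_advantage_pct']:.1f}%",
        f"- paired t = {result['comparison'].t_stat:.3f}, "
        f"p = {result['comparison'].p_two_sided:.4g}",
        f"- BF10 = {result['comparison'].bf10:.4g} "
        f"({result['comparison'].kr_category})",
        "",
    ]
    (outdir / "report.md").write_text("\n".join(lines))
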
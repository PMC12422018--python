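"""Parameter and result I/O: YAML parameter files, CSV/JSON outputs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .fitting import CommunitySpec, ObservedSummary
from .imaging import AnalysisConfig
from .model import CommunityPrediction, EnvironmentParams

__all__ = [
    "load_community_yaml",
    "load_analysis_config",
    "load_observed_csv",
    "prediction_to_record",
    "predictions_to_csv",
    "config_hash",
]


def load_community_yaml(path: str | Path) -> tuple[CommunitySpec, dict[str, float] | None]:
    """Read model parameters from YAML.

    Expected layout::

        environment: {rho: 0.65, D: 2.0e5, L: 3.0, W: 1.0}
        community:
          mu_dP: 0.5
          mu_dT: 0.5
          I_C: 10.0
          u_pro: 1000.0          # or u_pro_dP / u_pro_dT separately
          u_trp: 1000.0
        leakage:                  # optional
          proline: 0.1
          tryptophan: 0.02

    Returns the community spec and, if present, the leakage rates.
    """
    data = yaml.safe_load(Path(path).read_text())
    e = data["environment"]
    env = EnvironmentParams(cell_density=float(e["rho"]),
                            diffusion_D=float(e["D"]),
                            cell_length=float(e["L"]),
                            cell_width=float(e["W"]))
    c = data["community"]
    kw = dict(env=env, mu_dP=float(c["mu_dP"]), mu_dT=float(c["mu_dT"]),
              I_C=float(c["I_C"]))
    if "u_pro" in c:
        kw.update(u_pro_dP=float(c["u_pro"]), u_pro_dT=float(c["u_pro"]))
    else:
        kw.update(u_pro_dP=float(c["u_pro_dP"]), u_pro_dT=float(c["u_pro_dT"]))
    if "u_trp" in c:
        kw.update(u_trp_dT=float(c["u_trp"]), u_trp_dP=float(c["u_trp"]))
    else:
        kw.update(u_trp_dT=float(c["u_trp_dT"]), u_trp_dP=float(c["u_trp_dP"]))
    spec = CommunitySpec(**kw)
    leak = data.get("leakage")
    if leak is not None:
        leak = {k: float(v) for k, v in leak.items()}
    return spec, leak


def load_analysis_config(path: str | Path | None) -> AnalysisConfig:
    """Read image-analysis settings from YAML (missing keys keep defaults)."""
    cfg = AnalysisConfig()
    if path is None:
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    img = data.get("imaging", data)
    if "pixel_size" in img:
        cfg.pixel_size = float(img["pixel_size"])
    if "rho_c" in img:
        cfg.rho_c = float(img["rho_c"])
    if "band" in img:
        lo, hi = img["band"]
        cfg.band = (float(lo), float(hi))
    if "autocorr_threshold" in img:
        cfg.autocorr_threshold = float(img["autocorr_threshold"])
    if "channel_names" in img:
        cfg.channel_names = tuple(img["channel_names"])
    if "use_binary_signal" in img:
        cfg.use_binary_signal = bool(img["use_binary_signal"])
    if "background_subtract" in img:
        cfg.background_subtract = bool(img["background_subtract"])
    return cfg


def load_observed_csv(path: str | Path) -> list[ObservedSummary]:
    """Observed summaries CSV: community_label, f_dP_obs[, r_rel_obs]."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        r = row.get("r_rel_obs")
        r = None if (r is None or pd.isna(r)) else float(r)
        out.append(ObservedSummary(community_label=str(row["community_label"]),
                                   f_dP_obs=float(row["f_dP_obs"]),
                                   r_rel_obs=r))
    return out


def prediction_to_record(label: str, pred: CommunityPrediction) -> dict:
    return {
        "community_label": label,
        "f_dP": pred.f_dP, "f_dP_raw": pred.f_dP_raw, "r_rel": pred.r_rel,
        "R_int_pro": pred.range_dP.R_int, "R_int_trp": pred.range_dT.R_int,
        "r0_pro": pred.range_dP.r_0, "r0_trp": pred.range_dT.r_0,
        "N_dP": pred.N_dP, "N_dT": pred.N_dT,
        "mu_hat_dP": pred.cap_dP.mu_hat, "mu_hat_dT": pred.cap_dT.mu_hat,
        "flags": ";".join(pred.validity_flags),
    }


def predictions_to_csv(path: str | Path,
                       predictions: dict[str, CommunityPrediction]) -> None:
    pd.DataFrame([prediction_to_record(k, v)
                  for k, v in predictions.items()]).to_csv(path, index=False)


def config_hash(*objects) -> str:
    """Stable short hash of resolved configuration, embedded in reports."""
    blob = json.dumps([repr(o) for o in objects], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
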
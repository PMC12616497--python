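"""Declarative structural equation model and model-implied moments.

The model family is a linear latent-variable SEM with a measurement part
(each observed variable loads on exactly one latent) and a structural part
(a directed acyclic graph of paths among latents).  Moments are computed by
the reduced form

    V_eta  = (I - B)^-1 Psi (I - B)^-T        (latent covariance)
    Sigma  = Lambda V_eta Lambda^T + Theta    (observed covariance)
    mu     = nu                                (latent means fixed at zero)

where B collects structural coefficients, Psi the disturbance (co)variances
of the latents, Lambda the loadings, Theta the diagonal residual variances
and nu the observed intercepts.  One code path serves any acyclic structure,
including both candidate orientations of the global-severity construct.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import OBSERVED_VARS

LATENTS: tuple[str, ...] = ("communication", "comorbidities", "global")

# Default measurement structure: which latent each observed variable
# reflects, in canonical observed order.
MEASUREMENT: dict[str, str] = {
    "motor": "global",
    "insomnia": "comorbidities",
    "sleepiness": "comorbidities",
    "seizures": "comorbidities",
    "alertness": "comorbidities",
    "comm_clinician": "communication",
    "csbs": "communication",
    "vision": "global",
    "feeding": "global",
}

# First indicator of each latent; its loading is fixed to 1 for scale
# identification.
ANCHORS: dict[str, str] = {
    "global": "motor",
    "comorbidities": "insomnia",
    "communication": "comm_clinician",
}


class ModelSpecError(ValueError):
    """Invalid model structure (cycle, identification, indicator clash)."""


@dataclass
class SemModel:
    """Structure of a linear SEM with single-latent indicators.

    Parameters are laid out in a fixed flat order (see
    :meth:`param_names`): free loadings, structural coefficients, free
    disturbance (co)variances, residual variances, intercepts.
    """

    observed: tuple[str, ...]
    latents: tuple[str, ...]
    #: indicator -> (latent, fixed loading value or None when free)
    loadings: dict[str, tuple[str, float | None]]
    #: (source latent, target latent) pairs with free coefficients
    structural: tuple[tuple[str, str], ...]
    #: free entries of the latent disturbance covariance Psi
    psi_free: tuple[tuple[str, str], ...]
    #: fixed entries of Psi, e.g. a unit latent variance
    psi_fixed: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.observed = tuple(self.observed)
        self.latents = tuple(self.latents)
        self.structural = tuple(tuple(e) for e in self.structural)
        self.psi_free = tuple(tuple(e) for e in self.psi_free)
        self.psi_fixed = {tuple(k): float(v) for k, v in self.psi_fixed.items()}
        self._validate()
        self._names = self._build_layout()

    # -- validation ---------------------------------------------------
    def _validate(self) -> None:
        if len(set(self.observed)) != len(self.observed):
            raise ModelSpecError("duplicate observed variable names")
        seen: dict[str, str] = {}
        for var, (lat, _) in self.loadings.items():
            if var not in self.observed:
                raise ModelSpecError(f"loading for unknown observed variable {var!r}")
            if lat not in self.latents:
                raise ModelSpecError(f"loading on unknown latent {lat!r}")
            if var in seen:
                raise ModelSpecError(f"observed variable {var!r} assigned to two latents")
            seen[var] = lat
        missing = set(self.observed) - set(seen)
        if missing:
            raise ModelSpecError(f"observed variables without a latent: {sorted(missing)}")

        # acyclicity of the structural graph by iterative source removal
        edges = set(self.structural)
        nodes = set(self.latents)
        while nodes:
            sinks_removed = False
            for n in list(nodes):
                if not any(src == n and tgt in nodes for src, tgt in edges):
                    nodes.discard(n)
                    sinks_removed = True
            if not sinks_removed:
                raise ModelSpecError(f"structural graph has a cycle among {sorted(nodes)}")

        # identification: each latent needs one fixed loading or fixed variance
        for lat in self.latents:
            fixed_load = any(
                l == lat and val is not None for l, val in self.loadings.values()
            )
            fixed_var = (lat, lat) in self.psi_fixed
            if not (fixed_load or fixed_var):
                raise ModelSpecError(
                    f"latent {lat!r} is unidentified: fix one loading or its variance"
                )

    # -- parameter layout ---------------------------------------------
    def _build_layout(self) -> list[tuple[str, object]]:
        names: list[tuple[str, object]] = []
        for var in self.observed:
            lat, val = self.loadings[var]
            if val is None:
                names.append(("loading", var))
        for edge in self.structural:
            names.append(("beta", edge))
        for pair in self.psi_free:
            names.append(("psi", pair))
        for var in self.observed:
            names.append(("resid_var", var))
        for var in self.observed:
            names.append(("intercept", var))
        return names

    def param_names(self) -> list[str]:
        out = []
        for kind, key in self._names:
            if kind in ("beta", "psi"):
                out.append(f"{kind}:{key[0]}->{key[1]}" if kind == "beta" else f"psi:{key[0]},{key[1]}")
            else:
                out.append(f"{kind}:{key}")
        return out

    @property
    def n_params(self) -> int:
        return len(self._names)

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def df(self) -> int:
        """Degrees of freedom against the saturated mean+covariance model."""
        p = self.n_observed
        return p * (p + 3) // 2 - self.n_params

    def param_slices(self) -> dict[str, slice]:
        kinds = [k for k, _ in self._names]
        out = {}
        for kind in ("loading", "beta", "psi", "resid_var", "intercept"):
            idx = [i for i, k in enumerate(kinds) if k == kind]
            out[kind] = idx
        return out

    def variance_param_mask(self) -> np.ndarray:
        """Boolean mask over theta marking parameters that must stay > 0."""
        mask = np.zeros(self.n_params, dtype=bool)
        for i, (kind, key) in enumerate(self._names):
            if kind == "resid_var":
                mask[i] = True
            elif kind == "psi" and key[0] == key[1]:
                mask[i] = True
        return mask

    # -- matrix assembly ----------------------------------------------
    def matrices(self, theta: np.ndarray):
        """Assemble (Lambda, B, Psi, theta_diag, nu) from a flat vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(
                f"theta has length {theta.size}, model expects {self.n_params}"
            )
        if not np.all(np.isfinite(theta)):
            raise ValueError("non-finite entries in theta")
        p, L = len(self.observed), len(self.latents)
        lat_idx = {l: i for i, l in enumerate(self.latents)}
        obs_idx = {v: i for i, v in enumerate(self.observed)}

        Lam = np.zeros((p, L))
        B = np.zeros((L, L))
        Psi = np.zeros((L, L))
        theta_diag = np.zeros(p)
        nu = np.zeros(p)

        for (a, b), val in self.psi_fixed.items():
            Psi[lat_idx[a], lat_idx[b]] = val
            Psi[lat_idx[b], lat_idx[a]] = val
        for var, (lat, val) in self.loadings.items():
            if val is not None:
                Lam[obs_idx[var], lat_idx[lat]] = val

        for value, (kind, key) in zip(theta, self._names):
            if kind == "loading":
                lat = self.loadings[key][0]
                Lam[obs_idx[key], lat_idx[lat]] = value
            elif kind == "beta":
                src, tgt = key
                B[lat_idx[tgt], lat_idx[src]] = value
            elif kind == "psi":
                a, b = key
                Psi[lat_idx[a], lat_idx[b]] = value
                Psi[lat_idx[b], lat_idx[a]] = value
            elif kind == "resid_var":
                theta_diag[obs_idx[key]] = value
            else:
                nu[obs_idx[key]] = value
        return Lam, B, Psi, theta_diag, nu

    def pack(self, *, loadings=None, beta=None, psi=None, resid_var=None,
             intercept=None, default=0.0) -> np.ndarray:
        """Build a theta vector from keyword dicts (missing entries -> default)."""
        loadings = loadings or {}
        beta = beta or {}
        psi = {tuple(k): v for k, v in (psi or {}).items()}
        resid_var = resid_var or {}
        intercept = intercept or {}
        out = np.full(self.n_params, default, dtype=float)
        for i, (kind, key) in enumerate(self._names):
            src = {"loading": loadings, "beta": beta, "psi": psi,
                   "resid_var": resid_var, "intercept": intercept}[kind]
            if key in src:
                out[i] = src[key]
        return out

    def theta_dict(self, theta: np.ndarray) -> dict[str, float]:
        return dict(zip(self.param_names(), np.asarray(theta, float)))


@dataclass
class ImpliedMoments:
    mean: np.ndarray          # length-p mu(theta)
    cov: np.ndarray           # p x p Sigma(theta), symmetric
    latent_cov: np.ndarray    # L x L V_eta(theta)
    lam: np.ndarray           # p x L loading matrix


def implied_moments(model: SemModel, theta: np.ndarray) -> ImpliedMoments:
    """Model-implied mean vector and covariance matrix at theta.

    Residual variances must be strictly positive; non-positive values are
    flagged as inadmissible with a ValueError.
    """
    Lam, B, Psi, theta_diag, nu = model.matrices(theta)
    if np.any(theta_diag <= 0):
        raise ValueError("inadmissible theta: residual variance <= 0")
    eye = np.eye(len(model.latents))
    inv = np.linalg.solve(eye - B, eye)
    V = inv @ Psi @ inv.T
    V = (V + V.T) / 2.0
    Sigma = Lam @ V @ Lam.T + np.diag(theta_diag)
    Sigma = (Sigma + Sigma.T) / 2.0
    return ImpliedMoments(mean=nu, cov=Sigma, latent_cov=V, lam=Lam)


def default_cdd_model() -> SemModel:
    """The canonical severity model.

    Two exogenous latents (communication and comorbidities) with a free
    covariance feed one endogenous global-severity latent; motor, vision and
    feeding are direct indicators of global severity.  The first indicator
    of every latent carries a fixed unit loading.
    """
    loadings = {
        var: (lat, 1.0 if ANCHORS[lat] == var else None)
        for var, lat in MEASUREMENT.items()
    }
    return SemModel(
        observed=OBSERVED_VARS,
        latents=LATENTS,
        loadings=loadings,
        structural=(("communication", "global"), ("comorbidities", "global")),
        psi_free=(
            ("communication", "communication"),
            ("comorbidities", "comorbidities"),
            ("communication", "comorbidities"),
            ("global", "global"),
        ),
    )


def second_order_model() -> SemModel:
    """Alternative orientation: global severity drives the two sub-latents."""
    loadings = {
        var: (lat, 1.0 if ANCHORS[lat] == var else None)
        for var, lat in MEASUREMENT.items()
    }
    return SemModel(
        observed=OBSERVED_VARS,
        latents=LATENTS,
        loadings=loadings,
        structural=(("global", "communication"), ("global", "comorbidities")),
        psi_free=(
            ("communication", "communication"),
            ("comorbidities", "comorbidities"),
            ("global", "global"),
        ),
    )


# ---------------------------------------------------------------------
# serialization

def model_to_dict(model: SemModel) -> dict:
    return {
        "observed": list(model.observed),
        "latents": list(model.latents),
        "measurement": [
            {"indicator": var, "latent": lat,
             **({"fixed": val} if val is not None else {})}
            for var, (lat, val) in model.loadings.items()
        ],
        "structural": [{"from": a, "to": b} for a, b in model.structural],
        "psi": {
            "free": [list(p) for p in model.psi_free],
            "fixed": [{"pair": list(k), "value": v} for k, v in model.psi_fixed.items()],
        },
    }


def model_from_dict(cfg: dict) -> SemModel:
    try:
        seen = [m["indicator"] for m in cfg["measurement"]]
        dup = {v for v in seen if seen.count(v) > 1}
        if dup:
            raise ModelSpecError(
                f"observed variables assigned to two latents: {sorted(dup)}")
        loadings = {
            m["indicator"]: (m["latent"], m.get("fixed"))
            for m in cfg["measurement"]
        }
        return SemModel(
            observed=tuple(cfg["observed"]),
            latents=tuple(cfg["latents"]),
            loadings=loadings,
            structural=tuple((e["from"], e["to"]) for e in cfg.get("structural", [])),
            psi_free=tuple(tuple(p) for p in cfg.get("psi", {}).get("free", [])),
            psi_fixed={
                tuple(item["pair"]): item["value"]
                for item in cfg.get("psi", {}).get("fixed", [])
            },
        )
    except KeyError as exc:
        raise ModelSpecError(f"model config missing section/field: {exc}") from exc


def parse_model_config(text_or_path: str | Path) -> SemModel:
    """Parse a YAML/JSON model config (string or file path) into a SemModel."""
    p = Path(str(text_or_path))
    if p.suffix in {".yaml", ".yml", ".json"} and p.exists():
        text = p.read_text()
    else:
        text = str(text_or_path)
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ModelSpecError("model config must be a mapping")
    return model_from_dict(cfg)


def save_model_config(model: SemModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False))


def load_packaged_model(name: str = "default_model.yaml") -> SemModel:
    text = importlib.resources.files("cddsev.data").joinpath(name).read_text()
    return parse_model_config(text)
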
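"""YAML configuration parsing shared by the CLI subcommands.

A config file declares variable roles, the analysis model, the inclusion
rule (stage-1 block), weight-model and imputation-model specifications, the
strategy pair, M and the seed.  Terms are written as strings, with ``:``
separating the factors of a product term (``"X2:X3"``).
"""

from __future__ import annotations

import hashlib
import json

import yaml

from .datamodel import ModelSpec
from .errors import ValidationError
from .imputation import MVNImputerSpec
from .strategies import StrategySpec
from .weights import WeightModelSpec


def parse_term(s) -> tuple[str, ...] | str:
    if isinstance(s, str) and ":" in s:
        return tuple(p.strip() for p in s.split(":"))
    return s


def parse_terms(terms) -> list:
    return [parse_term(t) for t in terms]


def parse_model(d: dict) -> ModelSpec:
    return ModelSpec(d["outcome"], parse_terms(d.get("terms", [])),
                     intercept=d.get("intercept", True))


def parse_formula(formula: str) -> ModelSpec:
    """Parse ``"Y ~ X2 + X3 + X2:X3"`` into a ModelSpec."""
    try:
        lhs, rhs = formula.split("~")
    except ValueError:
        raise ValidationError(f"formula {formula!r} must contain '~'") from None
    terms = [parse_term(t.strip()) for t in rhs.split("+") if t.strip() not in ("", "1")]
    return ModelSpec(lhs.strip(), terms)


def parse_weight_model(d: dict) -> WeightModelSpec:
    return WeightModelSpec(predictors=parse_terms(d["predictors"]),
                           link=d.get("link", "logistic"))


def parse_mvn_imputer(d: dict) -> MVNImputerSpec:
    conds = tuple(parse_model(c) for c in d.get("conditionals", []))
    return MVNImputerSpec(block=tuple(d["block"]), conditionals=conds)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return cfg


def strategy_from_config(cfg: dict) -> StrategySpec:
    strat = cfg.get("strategy", {})
    imp = cfg.get("imputer", {})
    wm = cfg.get("weight_model", {})
    stage1 = strat.get("stage1", "CC")
    stage2 = strat.get("stage2", "CC")
    block = cfg.get("inclusion", {}).get("block")
    if block is None:
        raise ValidationError("config must declare inclusion.block")
    imp2 = imp.get("stage2")
    return StrategySpec(
        stage1=stage1,
        stage2=stage2,
        stage1_block=tuple(block),
        imputer1=parse_mvn_imputer(imp["stage1"]) if stage1 == "MI" else None,
        imputer2=parse_model(imp2) if (stage2 == "MI" and imp2) else None,
        weight_model1=parse_weight_model(wm["stage1"]) if stage1 == "IPW" else None,
        weight_model2=parse_weight_model(wm["stage2"]) if stage2 == "IPW" else None,
        M=int(cfg.get("M", 10)),
        label=strat.get("label", f"{stage1}/{stage2}"),
    )


def roles_from_config(cfg: dict) -> dict:
    return {v: tuple(r) for v, r in (cfg.get("roles") or {}).items()}


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
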
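"""Assemble named model variants; count parameters and MACs; audit budgets.

Variant zoo (11-class heads unless stated otherwise):

===========  ==================================================================
name         architecture
===========  ==================================================================
MS           MobileNetV3-Small as published (SE attention)
MS-ECA       every SE gate replaced by ECA
MS-CBAM      every SE gate replaced by CBAM (channel reduction 4)
MS-CA        every SE gate replaced by coordinate attention (CA-Block)
MS-CA-I      CA backbone, last stage replaced by a conventional Inception block
ICS-MS-CE    CA backbone + ICS-Inception fusion stage, cross-entropy head only
ICS-MS       ICS-MS-CE plus the center-feature projection head (joint loss)
===========  ==================================================================

plus the reference baselines ``resnet50``, ``mobilenet_v2``,
``mobilenet_v3_large`` and ``shufflenet_v2_x1_0``.

MAC counting follows the profiler convention common in the lightweight-CNN
literature: one multiply-accumulate per weight multiply, conv and linear
layers only, reported in G at 224x224x3 under the column label "FLOPs(G)".
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import yaml

from . import baselines
from .attention import AttentionKind, make_ca_block
from .backbone import (BackboneConfig, GrapeLeafNet, MOBILENET_V3_SMALL_ROWS,
                       STAGE2_END)
from .fusion import (ConventionalInception, ICSInception, ICS_INCEPTION_DEFAULT,
                     InceptionConfig)
from .nn import core
from .nn.layers import Module, count_parameters

#: dimension of the projected center feature (576 -> 85); pinned so the
#: joint-loss head adds the published ~0.05 M parameters (see docs/methods.md)
CENTER_DIM = 85

VARIANTS = ("MS", "MS-ECA", "MS-CBAM", "MS-CA", "MS-CA-I", "ICS-MS-CE",
            "ICS-MS")
BASELINES = ("resnet50", "mobilenet_v2", "mobilenet_v3_large",
             "shufflenet_v2_x1_0")


def _rows_with_attention(kind: AttentionKind):
    out = []
    for row in MOBILENET_V3_SMALL_ROWS:
        if row.attention == AttentionKind.SE:
            out.append(dataclasses.replace(row, attention=kind))
        else:
            out.append(row)
    return tuple(out)


def _ca_rows():
    return tuple(make_ca_block(r) for r in MOBILENET_V3_SMALL_ROWS)


def build_variant(name: str, num_classes: int = 11, seed: int = 0) -> Module:
    """Build a named variant; deterministic for a given seed."""
    if name not in VARIANTS:
        raise ValueError(
            f"unknown variant {name!r}; valid names: {', '.join(VARIANTS)}")
    rng_seed = seed

    if name in ("MS", "MS-ECA", "MS-CBAM", "MS-CA"):
        kind = {"MS": AttentionKind.SE, "MS-ECA": AttentionKind.ECA,
                "MS-CBAM": AttentionKind.CBAM,
                "MS-CA": AttentionKind.CA}[name]
        cfg = BackboneConfig(rows=_rows_with_attention(kind),
                             num_classes=num_classes)
        return GrapeLeafNet(cfg, seed=rng_seed, name=name)

    cfg = BackboneConfig(rows=_ca_rows(), num_classes=num_classes)
    fusion_rng = np.random.default_rng(seed + 1000)
    if name == "MS-CA-I":
        fusion = ConventionalInception(InceptionConfig(), rng=fusion_rng)
    else:
        fusion = ICSInception(ICS_INCEPTION_DEFAULT, rng=fusion_rng)
    center_dim = CENTER_DIM if name == "ICS-MS" else None
    return GrapeLeafNet(cfg, blocks_end=9, fusion=fusion, use_head_conv=False,
                        center_dim=center_dim, seed=rng_seed, name=name)


def build_baseline(name: str, num_classes: int = 11, seed: int = 0) -> Module:
    if name not in BASELINES:
        raise ValueError(
            f"unknown baseline {name!r}; valid names: {', '.join(BASELINES)}")
    cls = {"resnet50": baselines.ResNet50,
           "mobilenet_v2": baselines.MobileNetV2,
           "mobilenet_v3_large": baselines.MobileNetV3Large,
           "shufflenet_v2_x1_0": baselines.ShuffleNetV2}[name]
    return cls(num_classes=num_classes, seed=seed)


def insert_ics_inception(backbone_cfg: BackboneConfig, fusion_cfg=None,
                         center_dim: int | None = None,
                         seed: int = 0) -> GrapeLeafNet:
    """Assemble a model whose final stage is an ICS-Inception block.

    The fusion stage replaces the last bottleneck stage and the head conv;
    its concatenated width must equal the classifier input width (a
    configuration error otherwise).
    """
    from .fusion import ICSInception
    fusion_cfg = fusion_cfg or ICS_INCEPTION_DEFAULT
    fusion_cfg.validate()
    fusion = ICSInception(fusion_cfg, rng=np.random.default_rng(seed + 1000))
    return GrapeLeafNet(backbone_cfg, blocks_end=9, fusion=fusion,
                        use_head_conv=False, center_dim=center_dim,
                        seed=seed, name="ICS-MS" if center_dim else
                        "ICS-MS-CE")


def build(name: str, num_classes: int = 11, seed: int = 0) -> Module:
    if name in VARIANTS:
        return build_variant(name, num_classes, seed)
    return build_baseline(name, num_classes, seed)


# ------------------------------------------------------------- accounting

def count_macs(model: Module, image_size: int = 224) -> int:
    """Multiply-accumulates of one forward pass at batch 1 (conv + linear)."""
    model.eval()
    x = np.zeros((1, 3, image_size, image_size), dtype=np.float32)
    with core.count_macs_enabled() as counter:
        model(x)
    return counter[0]


def to_millions(n: int, decimals: int = 2) -> float:
    return round(n / 1e6, decimals)


def to_giga(n: int, decimals: int = 2) -> float:
    return round(n / 1e9, decimals)


def reduction_percent(base_printed: float, new_printed: float) -> float:
    """Headline reduction quoted from printed-precision budgets, truncated at
    one decimal — the quoting convention of the published tables."""
    return math.floor((base_printed - new_printed) / base_printed * 1000) / 10


@dataclasses.dataclass
class BudgetRow:
    name: str
    params: int
    params_m: float
    target_params_m: float | None
    macs: int | None
    macs_g: float | None
    target_macs_g: float | None
    passed: bool

    def delta_params(self) -> float | None:
        if self.target_params_m is None:
            return None
        return round(self.params_m - self.target_params_m, 4)


@dataclasses.dataclass
class BudgetReport:
    rows: list[BudgetRow]
    notes: dict

    @property
    def all_pass(self) -> bool:
        return all(r.passed for r in self.rows)

    def to_json(self) -> str:
        return json.dumps({
            "rows": [dataclasses.asdict(r) for r in self.rows],
            "notes": self.notes, "all_pass": self.all_pass}, indent=2)


def default_targets_path() -> Path:
    return Path(__file__).parent / "data" / "targets.yaml"


def load_targets(path: str | Path | None = None) -> list[dict]:
    path = Path(path) if path else default_targets_path()
    with open(path) as fh:
        return yaml.safe_load(fh)["targets"]


def audit_budgets(targets: list[dict] | None = None, num_classes: int = 11,
                  image_size: int = 224) -> BudgetReport:
    """Build every targeted model and compare rounded budgets.

    Each target: ``{name, params_M?, params_decimals?, macs_G?}``.
    """
    if targets is None:
        targets = load_targets()
    rows = []
    built = {}
    for t in targets:
        name = t["name"]
        model = built.setdefault(name, build(name, num_classes=num_classes))
        params = count_parameters(model)
        dec = int(t.get("params_decimals", 2))
        params_m = to_millions(params, dec)
        tp = t.get("params_M")
        ok = tp is None or params_m == tp
        macs = macs_g = tg = None
        if "macs_G" in t or t.get("count_macs"):
            macs = count_macs(model, image_size)
            macs_g = to_giga(macs)
            tg = t.get("macs_G")
            ok = ok and (tg is None or macs_g == tg)
        rows.append(BudgetRow(name, params, params_m, tp, macs, macs_g, tg, ok))

    by_name = {r.name: r for r in rows}
    notes = {"ics_inception_widths": {
        b.kind: [b.out_channels, b.hidden_channels]
        for b in ICS_INCEPTION_DEFAULT.branches},
        "center_dim": CENTER_DIM, "ca_reduction": 9}
    if "MS" in by_name and "MS-CA" in by_name:
        notes["reduction_MS_to_MS-CA_pct"] = reduction_percent(
            by_name["MS"].params_m, by_name["MS-CA"].params_m)
        notes["reduction_MS_to_MS-CA_exact_pct"] = round(
            100 * (by_name["MS"].params - by_name["MS-CA"].params)
            / by_name["MS"].params, 2)
    if "MS" in by_name and "ICS-MS" in by_name:
        notes["reduction_MS_to_ICS-MS_pct"] = reduction_percent(
            by_name["MS"].params_m, by_name["ICS-MS"].params_m)
        notes["reduction_MS_to_ICS-MS_exact_pct"] = round(
            100 * (by_name["MS"].params - by_name["ICS-MS"].params)
            / by_name["MS"].params, 2)
    return BudgetReport(rows, notes)


# ---------------------------------------------------------- serialization

def save_model(model: Module, path: str | Path) -> None:
    """Weights + an embedded manifest (variant, classes, audit numbers)."""
    manifest = {"name": getattr(model, "name", model.__class__.__name__),
                "num_classes": _num_classes_of(model),
                "params": count_parameters(model)}
    state = model.state_dict()
    np.savez_compressed(path, __manifest__=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **state)


def load_model(path: str | Path, num_classes: int | None = None) -> Module:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        state = {k: data[k] for k in data.files if k != "__manifest__"}
    if num_classes is not None and manifest["num_classes"] != num_classes:
        raise ValueError(
            f"checkpoint was trained with {manifest['num_classes']} classes, "
            f"requested {num_classes}")
    model = build(manifest["name"], num_classes=manifest["num_classes"])
    if count_parameters(model) != manifest["params"]:
        raise ValueError("checkpoint manifest does not match rebuilt "
                         "architecture (parameter count differs)")
    model.load_state_dict(state)
    return model


def _num_classes_of(model: Module) -> int:
    if hasattr(model, "config"):
        return model.config.num_classes
    if hasattr(model, "fc"):
        return model.fc.out_features
    return model.fc2.out_features
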
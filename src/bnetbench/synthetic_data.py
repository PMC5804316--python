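"""Synthetic compound datasets with the structure the analysis assumes.

The generator produces compound panels whose statistical shape mirrors
the published screening datasets: log-spread IC50s across up to seven
currents with activity concentrated on IKr, then ICaL, then late INa;
a log-spread free therapeutic concentration per compound; and risk
labels drawn from a logistic link on the compound's true net-block
score, P(risk) = expit(alpha + beta * B_net).  Because the label model
uses B_net as the genuine risk driver, parameter recovery and the
discrimination ordering of metrics are well-posed on generated data.

CredibleMeds categories are assigned conditional on the risk draw
(positives split KR/PR, negatives CR/NR), so the two classification
schemes genuinely differ on synthetic data.  Synthetic ΔAPD90 columns,
when requested, are a documented stand-in: a noisy linear transform of
the masked B_net, not a biophysical simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .bnet_score import bnet
from .block_transform import blocks_for_compound
from .channels import ChannelRegistry, DEFAULT_REGISTRY, THREE_CHANNEL_SET
from .classify_eval import LogisticFit, fit_logistic
from .datasets_io import (
    BlockProfile,
    ClassificationScheme,
    CompoundRecord,
    PrecomputedMetrics,
    capability_mask,
    labels_for_scheme,
    write_ic50_dataset,
    write_precomputed_dataset,
)
from .errors import ValidationError

#: Per-channel probability that a compound shows measurable activity.
#: Ordered to emulate the observed screening pattern: most compounds hit
#: IKr, ICaL is the next most common target, late INa activity is
#: notable, the remaining currents are rarely hit.
DEFAULT_ACTIVITY_PROFILE = {
    "IKr": 0.90,
    "ICaL": 0.55,
    "INa_late": 0.40,
    "INa_peak": 0.30,
    "IKs": 0.15,
    "Ito": 0.15,
    "IK1": 0.10,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic panel; defaults are the study conditions."""

    n_compounds: int = 100
    channels: frozenset[str] = frozenset(DEFAULT_REGISTRY.channels)
    log10_ic50_range: tuple[float, float] = (-2.0, 2.0)  # µM
    log10_eftpc_range: tuple[float, float] = (-2.0, 1.0)  # µM
    activity_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_PROFILE)
    )
    link_intercept: float = -1.0
    link_slope: float = 3.0
    positive_mix: dict[str, float] = field(
        default_factory=lambda: {"KR": 0.7, "PR": 0.3}
    )
    negative_mix: dict[str, float] = field(
        default_factory=lambda: {"CR": 0.2, "NR": 0.8}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValidationError("n_compounds must be positive")
        unknown = self.channels - frozenset(DEFAULT_REGISTRY.channels)
        if unknown:
            raise ValidationError(f"unknown channels: {sorted(unknown)}")
        for name, rng in (("IC50", self.log10_ic50_range),
                          ("EFTPC", self.log10_eftpc_range)):
            if not rng[0] < rng[1]:
                raise ValidationError(f"degenerate log10 {name} range: {rng}")
        for channel, p in self.activity_profile.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"activity probability out of range for {channel}")
        for mix in (self.positive_mix, self.negative_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
                raise ValidationError(f"category mix is not a distribution: {mix}")


def three_channel_config(**overrides) -> GeneratorConfig:
    """Config for the 3-channel assay-panel shape (hERG, Cav 1.2, Nav 1.5 peak)."""
    overrides.setdefault("channels", frozenset(THREE_CHANNEL_SET))
    return GeneratorConfig(**overrides)


def _draw_category(rng: np.random.Generator, mix: dict[str, float]) -> str:
    names = sorted(mix)
    return str(rng.choice(names, p=[mix[n] for n in names]))


def generate(
    config: GeneratorConfig, registry: ChannelRegistry = DEFAULT_REGISTRY
) -> tuple[list[CompoundRecord], dict[str, str]]:
    """Draw a synthetic compound panel; bit-reproducible for a fixed seed.

    Per compound: active channels are sampled from the activity
    profile, IC50s log-uniformly for active channels, the EFTPC
    log-uniformly; the true B_net is computed through the real
    block/score pipeline; risk is Bernoulli(expit(alpha + beta*B_net));
    the CredibleMeds category is drawn conditional on risk.
    """
    rng = np.random.default_rng(config.seed)
    ordered_channels = [c for c in registry.channels if c in config.channels]
    lo_ic, hi_ic = config.log10_ic50_range
    lo_ef, hi_ef = config.log10_eftpc_range

    records: list[CompoundRecord] = []
    categories: dict[str, str] = {}
    for i in range(config.n_compounds):
        name = f"SYN-{i:04d}"
        eftpc = float(10.0 ** rng.uniform(lo_ef, hi_ef))
        ic50 = {}
        for channel in ordered_channels:
            p_active = config.activity_profile.get(channel, 0.0)
            if rng.random() < p_active:
                ic50[channel] = float(10.0 ** rng.uniform(lo_ic, hi_ic))
        record = CompoundRecord(name=name, ic50=ic50, eftpc=eftpc, category="NR")
        score = bnet(blocks_for_compound(record), registry, usable=config.channels).bnet
        risk = rng.random() < expit(config.link_intercept + config.link_slope * score)
        category = _draw_category(
            rng, config.positive_mix if risk else config.negative_mix
        )
        record = CompoundRecord(name=name, ic50=ic50, eftpc=eftpc, category=category)
        records.append(record)
        categories[name] = category
    return records, categories


def synthetic_apd90(
    records: list[CompoundRecord],
    config: GeneratorConfig,
    registry: ChannelRegistry = DEFAULT_REGISTRY,
) -> list[PrecomputedMetrics]:
    """Synthetic stand-in ΔAPD90 columns: noisy linear transforms of B_net.

    Each model-variant column is ``gain * B_net(masked channels) +
    noise`` with the variant's capability mask (the 3-channel variants
    see IKr/ICaL/peak INa only; the TT-like variant lacks late INa).
    This preserves the monotone relation to net block that the
    evaluation exercises while making no biophysical claim.
    """
    rng = np.random.default_rng(config.seed + 1)  # independent of the panel draw
    masks = {
        column: capability_mask(column, registry)
        for column in ("Ohara3", "TenTusscher3", "OharaAll", "TenTusscherAll")
    }
    gains = {"Ohara3": 40.0, "TenTusscher3": 35.0, "OharaAll": 40.0, "TenTusscherAll": 35.0}
    three_mode = config.channels <= THREE_CHANNEL_SET
    columns = ("Ohara3", "TenTusscher3") if three_mode else masks.keys()

    metrics = []
    for record in records:
        profile = blocks_for_compound(record)
        apd = {}
        for column in columns:
            score = bnet(profile, registry, usable=masks[column] & config.channels).bnet
            apd[column] = float(gains[column] * score + rng.normal(0.0, 4.0))
        metrics.append(PrecomputedMetrics(compound=record.name, apd90_change=apd))
    return metrics


def write_synthetic_dataset(
    config: GeneratorConfig,
    ic50_path: str | Path,
    precomputed_path: str | Path,
    registry: ChannelRegistry = DEFAULT_REGISTRY,
) -> tuple[list[CompoundRecord], dict[str, str]]:
    """Generate a panel and write both CSV dialects through the real writers."""
    records, categories = generate(config, registry)
    write_ic50_dataset(records, ic50_path, registry)
    profiles = [blocks_for_compound(r) for r in records]
    # restrict profiles to the generated channel set so absence round-trips
    profiles = [
        BlockProfile(p.compound, {c: v for c, v in p.block.items() if c in config.channels})
        for p in profiles
    ]
    metrics = synthetic_apd90(records, config, registry)
    write_precomputed_dataset(profiles, metrics, categories, precomputed_path, registry)
    return records, categories


def recover_link(
    records: list[CompoundRecord],
    categories: dict[str, str],
    scheme: ClassificationScheme,
    registry: ChannelRegistry = DEFAULT_REGISTRY,
) -> LogisticFit:
    """Refit the label link on generated data: labels on true B_net.

    Returns the full-data logistic fit; with the QT/TdeP scheme (whose
    positives are exactly the risk-positive categories) the slope and
    intercept estimate the generator's (alpha, beta).
    """
    labels = labels_for_scheme(categories, scheme)
    x, y = [], []
    for record in records:
        x.append(bnet(blocks_for_compound(record), registry).bnet)
        y.append(int(labels[record.name]))
    return fit_logistic(x, y)
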
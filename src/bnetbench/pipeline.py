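"""End-to-end orchestration: read -> block -> score -> label -> evaluate.

One run evaluates a set of risk metrics on one dataset under one
classification scheme and writes a table of LOOCV ROC AUCs in the
layout of the published comparison (metric columns: B_net, the two
biophysical models' ΔAPD90, hERG block), plus a plain-text manifest
recording the configuration and an input checksum so runs are
attributable and reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bnet_score import bnet
from .block_transform import blocks_for_compound
from .channels import ChannelRegistry, DEFAULT_REGISTRY, THREE_CHANNEL_SET
from .classify_eval import EvaluationTable, MetricVector, evaluate
from .datasets_io import (
    BlockProfile,
    SCHEMES,
    labels_for_scheme,
    read_ic50_dataset,
    read_precomputed_dataset,
)
from .errors import ConfigurationError, DomainError

logger = logging.getLogger(__name__)

METRICS = ("bnet", "ord_apd90", "tt_apd90", "herg_block")
#: ΔAPD90 column per (metric, channel mode).
_APD_COLUMN = {
    ("ord_apd90", "three"): "Ohara3",
    ("ord_apd90", "seven"): "OharaAll",
    ("tt_apd90", "three"): "TenTusscher3",
    ("tt_apd90", "seven"): "TenTusscherAll",
}


@dataclass(frozen=True)
class RunConfig:
    input_path: str
    dialect: str = "precomputed"  # "ic50" | "precomputed"
    scheme: str = "QT_TdeP"  # "QT_TdeP" | "TdeP"
    metrics: tuple[str, ...] = METRICS
    channel_mode: str = "seven"  # "three" | "seven"
    out_dir: str = "results"
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.dialect not in ("ic50", "precomputed"):
            raise ConfigurationError(f"unknown dialect: {self.dialect!r}")
        if self.scheme not in SCHEMES:
            raise ConfigurationError(f"unknown scheme: {self.scheme!r}")
        if self.channel_mode not in ("three", "seven"):
            raise ConfigurationError(f"unknown channel mode: {self.channel_mode!r}")
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ConfigurationError(f"unknown metrics: {sorted(unknown)}")
        if self.dialect == "ic50":
            apd = {"ord_apd90", "tt_apd90"} & set(self.metrics)
            if apd:
                raise ConfigurationError(
                    f"metrics {sorted(apd)} need precomputed ΔAPD90 columns; "
                    "the ic50 dialect does not carry them"
                )


def _usable(config: RunConfig, registry: ChannelRegistry) -> frozenset[str]:
    if config.channel_mode == "three":
        return frozenset(THREE_CHANNEL_SET)
    return frozenset(registry.channels)


def metric_vectors(
    config: RunConfig, registry: ChannelRegistry = DEFAULT_REGISTRY
) -> list[MetricVector]:
    """Build one MetricVector per requested metric from the input file."""
    if config.dialect == "ic50":
        records = read_ic50_dataset(config.input_path, registry)
        profiles = [blocks_for_compound(r) for r in records]
        categories = {r.name: r.category for r in records}
        apd_by_compound: dict[str, dict[str, float]] = {}
    else:
        profiles, precomputed, categories = read_precomputed_dataset(
            config.input_path, registry
        )
        apd_by_compound = {m.compound: m.apd90_change for m in precomputed}

    scheme = SCHEMES[config.scheme]
    labels = labels_for_scheme(categories, scheme)
    usable = _usable(config, registry)
    dataset = Path(config.input_path).stem
    by_name = {p.compound: p for p in profiles}
    order = [p.compound for p in profiles]

    vectors = []
    for metric in config.metrics:
        if metric == "bnet":
            values = {c: bnet(by_name[c], registry, usable=usable).bnet for c in order}
        elif metric == "herg_block":
            values = {c: bnet(by_name[c], registry, usable={"IKr"}).bnet for c in order}
        else:
            column = _APD_COLUMN[(metric, config.channel_mode)]
            values = {
                c: apd_by_compound[c][column]
                for c in order
                if column in apd_by_compound.get(c, {})
            }
            if not values:
                raise ConfigurationError(
                    f"no compound carries the {column} column required by {metric}"
                )
        compounds = tuple(c for c in order if c in values)
        vectors.append(
            MetricVector(
                compounds=compounds,
                x=tuple(values[c] for c in compounds),
                y=tuple(int(labels[c]) for c in compounds),
                metric_name=metric,
                scheme_name=scheme.name,
                dataset_name=dataset,
            )
        )
    return vectors


def run(config: RunConfig, registry: ChannelRegistry = DEFAULT_REGISTRY) -> EvaluationTable:
    """Execute one evaluation run and write its table and manifest."""
    vectors = metric_vectors(config, registry)
    table = evaluate(vectors)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_path = out_dir / f"evaluation_{config.scheme}.csv"
    pd.DataFrame(table.to_records()).to_csv(table_path, index=False)

    digest = hashlib.sha256(Path(config.input_path).read_bytes()).hexdigest()
    manifest = out_dir / "manifest.txt"
    manifest.write_text(
        "\n".join(
            [
                f"input_path: {config.input_path}",
                f"input_sha256: {digest}",
                f"dialect: {config.dialect}",
                f"scheme: {config.scheme}",
                f"metrics: {','.join(config.metrics)}",
                f"channel_mode: {config.channel_mode}",
                f"seed: {config.seed}",
                "",
            ]
        )
    )
    logger.info("wrote %s", table_path)
    return table


def summarise_blocks(
    profiles: list[BlockProfile], registry: ChannelRegistry = DEFAULT_REGISTRY
) -> pd.DataFrame:
    """Five-number summary of fractional block per channel.

    Quartiles use linear interpolation of order statistics.  Channels a
    compound did not measure are excluded from that channel's sample,
    not counted as zero.
    """
    if not profiles:
        raise DomainError("no block profiles supplied")
    rows = []
    for channel in registry.channels:
        values = np.array(
            [p.block[channel] for p in profiles if channel in p.block], dtype=float
        )
        if values.size == 0:
            continue
        q = np.percentile(values, [0, 25, 50, 75, 100], method="linear")
        rows.append(
            {
                "channel": channel,
                "n": values.size,
                "min": q[0],
                "q1": q[1],
                "median": q[2],
                "q3": q[3],
                "max": q[4],
            }
        )
    return pd.DataFrame(rows)
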
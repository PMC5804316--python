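"""Reading and writing compound datasets in the two CSV dialects.

Two schemas are supported, both comma-separated with a header row:

``ic50`` dialect
    ``compound, category, eftpc_uM, <channel>_ic50_uM, ...`` — raw
    half-maximal inhibitory concentrations plus the effective free
    therapeutic plasma concentration (EFTPC) per compound.  Empty IC50
    cells mean the channel was not measured (distinct from zero block).

``precomputed`` dialect
    ``compound, category, <channel>_block_pct, ..., Ohara3,
    TenTusscher3, OharaAll, TenTusscherAll`` — per-channel percent
    block at the EFTPC together with precomputed percent change in
    APD90 from the two biophysical cell models.  Any subset of the four
    ΔAPD90 columns may be present.

Internally block is always a fraction in [0, 1]; percent appears only
at the file boundary.  Risk categories follow the CredibleMeds levels
KR (known TdeP risk), PR (possible risk / known QT risk), CR
(conditional risk) and NR (not listed); a missing category means NR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .channels import ChannelRegistry, THREE_CHANNEL_SET
from .errors import FormatError, ValidationError

CATEGORIES = ("KR", "PR", "CR", "NR")

_CATEGORY_ALIASES = {
    "kr": "KR",
    "known risk": "KR",
    "known risk (kr)": "KR",
    "pr": "PR",
    "possible risk": "PR",
    "possible risk (pr)": "PR",
    "cr": "CR",
    "conditional risk": "CR",
    "conditional risk (cr)": "CR",
    "nr": "NR",
    "no risk": "NR",
    "no risk (nr)": "NR",
    "not listed": "NR",
}

#: Names of the precomputed ΔAPD90 columns (percent change, signed).
APD90_COLUMNS = ("Ohara3", "TenTusscher3", "OharaAll", "TenTusscherAll")


@dataclass(frozen=True)
class CompoundRecord:
    """One drug: per-channel IC50s (µM, possibly absent), EFTPC (µM), risk category."""

    name: str
    ic50: dict[str, float]
    eftpc: float
    category: str = "NR"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.eftpc) and self.eftpc > 0):
            raise ValidationError(f"{self.name}: EFTPC must be positive, got {self.eftpc}")
        for channel, value in self.ic50.items():
            if not (math.isfinite(value) and value > 0):
                raise ValidationError(
                    f"{self.name}: IC50 for {channel} must be positive, got {value}"
                )
        if self.category not in CATEGORIES:
            raise ValidationError(f"{self.name}: unknown category {self.category!r}")


@dataclass(frozen=True)
class BlockProfile:
    """Fractional block per measured channel for one compound at its EFTPC.

    Absent channels are simply missing from ``block`` — absence is
    recorded explicitly rather than coerced to zero block.
    """

    compound: str
    block: dict[str, float]

    def __post_init__(self) -> None:
        for channel, value in self.block.items():
            if not (math.isfinite(value) and 0.0 <= value <= 1.0):
                raise ValidationError(
                    f"{self.compound}: block for {channel} must lie in [0, 1], got {value}"
                )


@dataclass(frozen=True)
class PrecomputedMetrics:
    """Signed percent change in APD90 per model variant for one compound."""

    compound: str
    apd90_change: dict[str, float]

    def __post_init__(self) -> None:
        for column, value in self.apd90_change.items():
            if column not in APD90_COLUMNS:
                raise FormatError(f"unknown ΔAPD90 column: {column!r}")
            if not math.isfinite(value):
                raise ValidationError(f"{self.compound}: non-finite ΔAPD90 in {column}")


@dataclass(frozen=True)
class ClassificationScheme:
    """Binary risk labelling rule over the CredibleMeds categories."""

    name: str
    positive_categories: frozenset[str]


#: Joint QT-prolongation / TdeP risk: KR and PR count as positive.
QT_TDEP = ClassificationScheme("QT_TdeP", frozenset({"KR", "PR"}))
#: Known-TdeP-risk-only scheme: only KR counts as positive.
TDEP = ClassificationScheme("TdeP", frozenset({"KR"}))

SCHEMES = {s.name: s for s in (QT_TDEP, TDEP)}


def parse_category(value: object) -> str:
    """Normalise a CredibleMeds category cell; blank cells map to NR."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NR"
    text = " ".join(str(value).strip().lower().split())
    if not text:
        return "NR"
    try:
        return _CATEGORY_ALIASES[text]
    except KeyError:
        raise ValidationError(f"unknown CredibleMeds category: {value!r}") from None


def labels_for_scheme(
    categories: dict[str, str], scheme: ClassificationScheme
) -> dict[str, bool]:
    """Map each compound's category to a binary label under ``scheme``."""
    labels = {}
    for compound, category in categories.items():
        canonical = parse_category(category)
        labels[compound] = canonical in scheme.positive_categories
    return labels


def capability_mask(metric_column: str, registry: ChannelRegistry) -> frozenset[str]:
    """Currents a model variant can use.

    The 3-channel variants were run with IKr, peak INa and ICaL only;
    the TT model does not include a late sodium current, so its
    all-channel variant covers six of the seven currents.
    """
    all_channels = frozenset(registry.channels)
    if metric_column == "OharaAll":
        return all_channels
    if metric_column == "TenTusscherAll":
        return all_channels - {"INa_late"}
    if metric_column in ("Ohara3", "TenTusscher3"):
        return frozenset(THREE_CHANNEL_SET)
    raise FormatError(f"unknown model variant: {metric_column!r}")


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_IC50_SUFFIX = "_ic50_um"
_BLOCK_SUFFIX = "_block_pct"


def _read_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, dtype={"compound": str}, skipinitialspace=True,
        float_precision="round_trip",
    )
    frame.columns = [str(c).strip() for c in frame.columns]
    lower = {c.lower(): c for c in frame.columns}
    if "compound" not in lower:
        raise FormatError(f"{path}: no 'compound' column")
    return frame.rename(columns={lower["compound"]: "compound"})


def _find_column(frame: pd.DataFrame, name: str) -> str | None:
    for column in frame.columns:
        if column.lower() == name:
            return column
    return None


def read_ic50_dataset(path: str | Path, registry: ChannelRegistry) -> list[CompoundRecord]:
    """Read the raw IC50 + EFTPC dialect into compound records.

    Channel columns are recognised by the ``_ic50_uM`` suffix and
    canonicalised via the registry aliases; an unresolvable channel
    column is a :class:`FormatError`, a non-positive concentration a
    :class:`ValidationError` naming the compound.
    """
    frame = _read_csv(path)
    eftpc_col = _find_column(frame, "eftpc_um") or _find_column(frame, "eftpc")
    if eftpc_col is None:
        raise FormatError(f"{path}: no EFTPC column")
    category_col = _find_column(frame, "category")

    channel_cols: dict[str, str] = {}
    for column in frame.columns:
        if column.lower().endswith(_IC50_SUFFIX):
            stem = column[: -len(_IC50_SUFFIX)]
            channel_cols[column] = registry.resolve(stem)  # FormatError if unknown
    if not channel_cols:
        raise FormatError(f"{path}: no channel IC50 columns found")

    records = []
    for _, row in frame.iterrows():
        name = str(row["compound"])
        ic50 = {}
        for column, channel in channel_cols.items():
            value = row[column]
            if pd.isna(value):
                continue
            ic50[channel] = float(value)
        records.append(
            CompoundRecord(
                name=name,
                ic50=ic50,
                eftpc=float(row[eftpc_col]),
                category=parse_category(row[category_col]) if category_col else "NR",
            )
        )
    return records


def write_ic50_dataset(
    records: list[CompoundRecord], path: str | Path, registry: ChannelRegistry
) -> None:
    """Write compound records in the raw IC50 dialect (inverse of the reader)."""
    rows = []
    for record in records:
        row: dict[str, object] = {
            "compound": record.name,
            "category": record.category,
            # shortest round-trip float representation so write->read is lossless
            "eftpc_uM": repr(float(record.eftpc)),
        }
        for channel in registry.channels:
            value = record.ic50.get(channel)
            row[f"{channel}_ic50_uM"] = "" if value is None else repr(float(value))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_precomputed_dataset(
    path: str | Path, registry: ChannelRegistry
) -> tuple[list[BlockProfile], list[PrecomputedMetrics], dict[str, str]]:
    """Read the precomputed dialect: percent block + ΔAPD90 + categories.

    Percent block is divided by 100 into fractional block; ΔAPD90 stays
    on its signed percent scale.  Block outside [0, 100] is a
    :class:`ValidationError`; a column that is neither a recognised
    block column, a ΔAPD90 column, nor compound/category is a
    :class:`FormatError`.
    """
    frame = _read_csv(path)
    category_col = _find_column(frame, "category")

    block_cols: dict[str, str] = {}
    apd_cols: list[str] = []
    for column in frame.columns:
        if column == "compound" or column == category_col:
            continue
        if column.lower().endswith(_BLOCK_SUFFIX):
            stem = column[: -len(_BLOCK_SUFFIX)]
            block_cols[column] = registry.resolve(stem)
        elif column in APD90_COLUMNS:
            apd_cols.append(column)
        else:
            raise FormatError(f"{path}: unrecognised column {column!r}")
    if not block_cols:
        raise FormatError(f"{path}: no percent-block columns found")

    profiles, metrics, categories = [], [], {}
    for _, row in frame.iterrows():
        name = str(row["compound"])
        block = {}
        for column, channel in block_cols.items():
            value = row[column]
            if pd.isna(value):
                continue
            pct = float(value)
            if not (0.0 <= pct <= 100.0):
                raise ValidationError(
                    f"{name}: percent block for {channel} outside [0, 100]: {pct}"
                )
            block[channel] = pct / 100.0
        profiles.append(BlockProfile(compound=name, block=block))
        apd = {c: float(row[c]) for c in apd_cols if not pd.isna(row[c])}
        metrics.append(PrecomputedMetrics(compound=name, apd90_change=apd))
        categories[name] = parse_category(row[category_col]) if category_col else "NR"
    return profiles, metrics, categories


def write_precomputed_dataset(
    profiles: list[BlockProfile],
    metrics: list[PrecomputedMetrics],
    categories: dict[str, str],
    path: str | Path,
    registry: ChannelRegistry,
) -> None:
    """Write the precomputed dialect (inverse of the reader, percent at the boundary)."""
    by_name = {m.compound: m for m in metrics}
    rows = []
    for profile in profiles:
        row: dict[str, object] = {
            "compound": profile.compound,
            "category": categories.get(profile.compound, "NR"),
        }
        for channel in registry.channels:
            value = profile.block.get(channel)
            row[f"{channel}_block_pct"] = "" if value is None else repr(value * 100.0)
        apd = by_name.get(profile.compound)
        if apd is not None:
            for column in APD90_COLUMNS:
                if column in apd.apd90_change:
                    row[column] = repr(apd.apd90_change[column])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
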
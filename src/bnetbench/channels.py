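"""Registry of the seven ventricular ionic currents and their roles.

The net-block score separates currents that repolarise the action
potential (IKr, IKs, Ito) from those that depolarise or sustain it
(ICaL, peak and late INa, IK1).  IK1 is deliberately placed in the
depolarising sum: that is the role assignment the score is defined
with, and the registry exposes the role map so a sensitivity analysis
can swap it without touching the scoring code.

Channel names arrive in several dialects (gene/protein names such as
"hERG" or "Cav 1.2", current names such as "IKr"); the registry
resolves them case-insensitively to canonical identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import FormatError

REPOLARISING = "repolarising"
DEPOLARISING = "depolarising"

#: Canonical identifiers, in display order.
CANONICAL_CHANNELS = ("IKr", "IKs", "Ito", "ICaL", "INa_peak", "INa_late", "IK1")

_ROLES = {
    "IKr": REPOLARISING,
    "IKs": REPOLARISING,
    "Ito": REPOLARISING,
    "ICaL": DEPOLARISING,
    "INa_peak": DEPOLARISING,
    "INa_late": DEPOLARISING,
    "IK1": DEPOLARISING,
}

# Alternate spellings, keyed by normalised (lower-case, squeezed) form.
_ALIASES = {
    "herg": "IKr",
    "ikr": "IKr",
    "kcnq1 + kcne1": "IKs",
    "kcnq1+kcne1": "IKs",
    "iks": "IKs",
    "kv4.3": "Ito",
    "ito": "Ito",
    "cav 1.2": "ICaL",
    "cav1.2": "ICaL",
    "ical": "ICaL",
    "nav1.5 peak": "INa_peak",
    "nav 1.5 peak": "INa_peak",
    "ina (peak)": "INa_peak",
    "ina peak": "INa_peak",
    "ina_peak": "INa_peak",
    "ina": "INa_peak",
    "nav1.5 late": "INa_late",
    "nav 1.5 late": "INa_late",
    "ina (late)": "INa_late",
    "ina late": "INa_late",
    "ina_late": "INa_late",
    "inal": "INa_late",
    "kir2.1": "IK1",
    "ik1": "IK1",
}

#: The three currents measured by the older assay panels (hERG, Cav 1.2,
#: Nav 1.5 peak) — also the channel subset the 3-channel model variants use.
THREE_CHANNEL_SET = frozenset({"IKr", "ICaL", "INa_peak"})


def _normalise(name: str) -> str:
    return " ".join(name.strip().lower().split())


@dataclass(frozen=True)
class ChannelRegistry:
    """Ordered set of currents with role tags and alias resolution."""

    channels: tuple[str, ...] = CANONICAL_CHANNELS
    role: dict[str, str] = field(default_factory=lambda: dict(_ROLES))
    aliases: dict[str, str] = field(default_factory=lambda: dict(_ALIASES))

    def __post_init__(self) -> None:
        missing = set(self.channels) - set(self.role)
        if missing:
            raise ValueError(f"channels without a role: {sorted(missing)}")
        bad = {c: r for c, r in self.role.items() if r not in (REPOLARISING, DEPOLARISING)}
        if bad:
            raise ValueError(f"invalid roles: {bad}")

    def resolve(self, name: str) -> str:
        """Map any accepted channel spelling to its canonical identifier.

        Resolution is case-insensitive and idempotent (a canonical name
        resolves to itself).  Unknown names raise :class:`FormatError`.
        """
        key = _normalise(name)
        if key in self.aliases:
            return self.aliases[key]
        for canonical in self.channels:
            if key == canonical.lower():
                return canonical
        raise FormatError(f"unknown channel name: {name!r}")

    def repolarising(self) -> frozenset[str]:
        return frozenset(c for c in self.channels if self.role[c] == REPOLARISING)

    def depolarising(self) -> frozenset[str]:
        return frozenset(c for c in self.channels if self.role[c] == DEPOLARISING)


#: Module-level default registry with the standard role assignment.
DEFAULT_REGISTRY = ChannelRegistry()
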
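"""The B_net linear net-block score.

B_net is the net difference in fractional block between repolarising
and depolarising currents:

    B_net = sum_i R_i - sum_j D_j

where R_i runs over the measured repolarising currents (IKr, IKs, Ito)
and D_j over the measured depolarising currents (ICaL, peak INa, late
INa, IK1).  Channels outside the usable mask (a model-capability or
assay-panel restriction) or not measured for a compound contribute
nothing.  Restricting the mask to {IKr} recovers plain hERG block, the
field's naive benchmark, as a special case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .channels import ChannelRegistry, DEFAULT_REGISTRY
from .datasets_io import BlockProfile
from .errors import DomainError


@dataclass(frozen=True)
class BnetResult:
    """Net-block score with the channel counts that entered each sum."""

    compound: str
    bnet: float
    n_repol_used: int
    n_depol_used: int


def bnet(
    profile: BlockProfile,
    registry: ChannelRegistry = DEFAULT_REGISTRY,
    usable: Iterable[str] | None = None,
) -> BnetResult:
    """Score one compound's block profile.

    Parameters
    ----------
    profile
        Fractional block per measured channel.
    registry
        Supplies the repolarising/depolarising role of each current.
    usable
        Channels the caller is allowed to use (defaults to all
        registry channels).  The sums run over usable ∩ measured.
    """
    usable_set = frozenset(registry.channels) if usable is None else frozenset(usable)
    unknown = usable_set - frozenset(registry.channels)
    if unknown:
        raise DomainError(f"usable channels not in registry: {sorted(unknown)}")

    repol_sum = depol_sum = 0.0
    n_repol = n_depol = 0
    for channel, value in profile.block.items():
        if channel not in usable_set:
            continue
        if not 0.0 <= value <= 1.0:
            raise DomainError(
                f"{profile.compound}: block for {channel} outside [0, 1]: {value}"
            )
        if channel in registry.repolarising():
            repol_sum += value
            n_repol += 1
        else:
            depol_sum += value
            n_depol += 1
    return BnetResult(
        compound=profile.compound,
        bnet=repol_sum - depol_sum,
        n_repol_used=n_repol,
        n_depol_used=n_depol,
    )


def herg_block(profile: BlockProfile, registry: ChannelRegistry = DEFAULT_REGISTRY) -> float:
    """The naive benchmark: fractional IKr (hERG) block, 0 if unmeasured.

    Equals ``bnet(profile, registry, usable={'IKr'}).bnet`` by construction.
    """
    return bnet(profile, registry, usable={"IKr"}).bnet
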
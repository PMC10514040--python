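"""Channel montages and named scalp region sets.

The study design uses the 64-channel BioSemi ActiveTwo layout (10-10 names).
Region sets name the channel groups where group differences in coupling are
planted by the synthetic generator and looked for by the statistics stage:
bilateral temporal/frontotemporal (lower coupling in the high-schizotypy-like
group) and occipital/parieto-occipital (higher coupling).
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Default region sets on the BioSemi-64 montage.
DEFAULT_REGION_SETS: dict[str, tuple[str, ...]] = {
    "temporal_frontotemporal_left": ("F7", "FT7", "FC5", "FC3", "T7", "C5", "TP7"),
    "temporal_frontotemporal_right": ("F8", "FT8", "FC6", "FC4", "T8", "C6", "TP8"),
    "occipital_parieto_occipital": ("PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2"),
    "prefrontal": ("Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8"),
}


@dataclass(frozen=True)
class MontageSpec:
    """Ordered channel labels plus named channel subsets (regions).

    Invariants: labels are unique; every region is a subset of the labels.
    """

    labels: tuple[str, ...]
    region_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        label_set = set(self.labels)
        for name, chans in self.region_sets.items():
            missing = set(chans) - label_set
            if missing:
                raise ValueError(
                    f"region {name!r} contains channels absent from montage: {sorted(missing)}"
                )

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def indices(self, labels) -> list[int]:
        return [self.labels.index(c) for c in labels]

    def region_indices(self, region: str) -> list[int]:
        return self.indices(self.region_sets[region])

    def subset(self, labels) -> "MontageSpec":
        """Montage restricted to ``labels`` (kept in the given order); regions
        are intersected with the retained channels."""
        keep = set(labels)
        regions = {
            name: tuple(c for c in chans if c in keep)
            for name, chans in self.region_sets.items()
        }
        regions = {k: v for k, v in regions.items() if v}
        return MontageSpec(labels=tuple(labels), region_sets=regions)


def biosemi64() -> MontageSpec:
    """The 64-channel BioSemi 10-10 montage with the default region sets."""
    import mne

    labels = tuple(mne.channels.make_standard_montage("biosemi64").ch_names)
    return MontageSpec(labels=labels, region_sets=dict(DEFAULT_REGION_SETS))
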
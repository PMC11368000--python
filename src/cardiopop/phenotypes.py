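"""Registry of the five cardiotoxicity phenotypes scored by the assay.

Each phenotype is read off a measurement channel (a vehicle-normalized
response ratio), has a fixed direction of adverse change, and a fixed
benchmark-response level defining its point of departure (POD):

* positive/negative chronotropy: 5% increase/decrease in spontaneous beat
  frequency relative to vehicle (EC05);
* QT-prolongation proxy: 5% increase in the calcium-transient
  decay-to-rise ratio (EC05);
* asystole: 95% decrease in beat frequency without cell loss (EC95);
* cytotoxicity: 10% decrease in nuclei count (EC10).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhenotypeDef:
    """Measurement channel, adverse direction and POD benchmark."""

    name: str
    channel: str           # column of the normalized-response table
    direction: str         # "increase" or "decrease"
    benchmark: str         # EC05 / EC10 / EC95

    @property
    def benchmark_change(self) -> float:
        return BENCHMARK_CHANGES[self.benchmark]


BENCHMARK_CHANGES = {"EC05": 0.05, "EC10": 0.10, "EC95": 0.95}

PHENOTYPES: dict[str, PhenotypeDef] = {
    p.name: p
    for p in (
        PhenotypeDef("positive_chronotrope", "beat_rate_ratio", "increase", "EC05"),
        PhenotypeDef("negative_chronotrope", "beat_rate_ratio", "decrease", "EC05"),
        PhenotypeDef("qt_prolongation", "decay_to_rise_ratio", "increase", "EC05"),
        PhenotypeDef("asystole", "beat_rate_ratio", "decrease", "EC95"),
        PhenotypeDef("cytotoxicity", "nuclei_ratio", "decrease", "EC10"),
    )
}

PHENOTYPE_NAMES = tuple(PHENOTYPES)
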
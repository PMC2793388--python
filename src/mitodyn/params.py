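"""Parameter bookkeeping: loading, adjustable flags, provenance tiers."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

__all__ = ["Parameter", "ParameterSet", "load_parameters", "TABLE2_COUNT"]

#: number of whole-model adjustable parameters
TABLE2_COUNT = 42


@dataclass
class Parameter:
    reaction: str
    symbol: str
    value: float
    units: str
    adjustable: bool
    tier: int
    description: str = ""

    @property
    def key(self):
        return (self.reaction, self.symbol)


@dataclass
class ParameterSet:
    """All model parameters, addressable as ``pset["PDH", "Vmax"]``.

    The adjustable subset is the whole-model calibration set (tier 3);
    everything else is fixed from literature or isolated rate-curve fits.
    """

    params: dict = field(default_factory=dict)

    def __getitem__(self, key) -> float:
        return self.params[key].value

    def __setitem__(self, key, value: float):
        self.params[key].value = float(value)

    def __contains__(self, key):
        return key in self.params

    def __len__(self):
        return len(self.params)

    def get(self, reaction, symbol, default=None):
        p = self.params.get((reaction, symbol))
        return default if p is None else p.value

    @property
    def adjustable_keys(self):
        return [k for k, p in self.params.items() if p.adjustable]

    def copy(self) -> "ParameterSet":
        out = ParameterSet()
        for k, p in self.params.items():
            out.params[k] = Parameter(p.reaction, p.symbol, p.value, p.units,
                                      p.adjustable, p.tier, p.description)
        return out

    def validate(self):
        bad = [k for k, p in self.params.items() if not p.value > 0
               and p.units != "J/mol"]
        if bad:
            raise ValueError(f"non-positive parameters: {bad}")
        n_adj = len(self.adjustable_keys)
        if n_adj != TABLE2_COUNT:
            raise ValueError(
                f"expected {TABLE2_COUNT} adjustable parameters, found "
                f"{n_adj}")
        return self


def load_parameters(path=None) -> ParameterSet:
    """Load the shipped parameter table (or a user-supplied override file)."""
    if path is None:
        text = resources.files("mitodyn.data").joinpath(
            "parameters.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    pset = ParameterSet()
    header = None
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        reaction, symbol, value, units, adjustable, tier, desc = parts
        p = Parameter(reaction, symbol, float(value), units,
                      adjustable == "1", int(tier), desc)
        if p.key in pset.params:
            raise ValueError(f"duplicate parameter {p.key}")
        pset.params[p.key] = p
    return pset.validate()
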
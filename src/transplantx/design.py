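"""Sample design of a two-generation reciprocal-transplant experiment.

Replicate laboratory populations ("lineages") are kept at one of three pCO2
levels (400, 900 and 1550 uatm) for two generations and the adults are then
reciprocally transplanted.  Each sequenced sample is a pool of individuals
identified by the pCO2 its lineage was raised at (*origin*), the pCO2 it was
moved to (*destination*) and a replicate label.  The emulated layout has
seven (origin, destination) treatments in two replicates, fourteen pools in
total:

    400->400  900->900  1550->1550        (natives)
    400->900  400->1550                   (control moved up)
    900->400  1550->400                   (acclimated/adapted moved back)
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DesignError

#: Nominal pCO2 levels (uatm) used in the study design.
PCO2_LEVELS = (400, 900, 1550)

#: The seven (origin, destination) treatments of the reciprocal transplant.
TREATMENTS = (
    (400, 400),
    (900, 900),
    (1550, 1550),
    (400, 900),
    (400, 1550),
    (900, 400),
    (1550, 400),
)


def treatment_key(origin: int, destination: int) -> str:
    """Canonical string form of a treatment, e.g. ``"400->1550"``."""
    return f"{origin}->{destination}"


def sample_name(origin: int, destination: int, replicate: str) -> str:
    """Sample id encoding treatment and replicate (``400A``, ``400-1550B``)."""
    if origin == destination:
        return f"{origin}{replicate}"
    return f"{origin}-{destination}{replicate}"


@dataclass(frozen=True)
class Sample:
    sample_id: str
    origin_pco2: int
    destination_pco2: int
    replicate: str
    pool_size: int

    def __post_init__(self):
        if self.origin_pco2 not in PCO2_LEVELS:
            raise DesignError(f"unknown origin pCO2 {self.origin_pco2}")
        if self.destination_pco2 not in PCO2_LEVELS:
            raise DesignError(f"unknown destination pCO2 {self.destination_pco2}")
        if self.pool_size < 1:
            raise DesignError(f"pool_size must be >= 1, got {self.pool_size}")

    @property
    def treatment(self) -> tuple[int, int]:
        return (self.origin_pco2, self.destination_pco2)


@dataclass
class SampleDesign:
    """An ordered collection of pooled samples with unique ids."""

    samples: list[Sample]

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DesignError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def treatments(self) -> set[tuple[int, int]]:
        return {s.treatment for s in self.samples}

    def samples_for(self, origin: int, destination: int) -> list[Sample]:
        return [s for s in self.samples if s.treatment == (origin, destination)]

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise DesignError(f"no sample named {sample_id!r} in design")

    def require_treatments(self, needed=TREATMENTS) -> None:
        """Raise :class:`DesignError` unless every requested treatment is present."""
        missing = [t for t in needed if not self.samples_for(*t)]
        if missing:
            names = ", ".join(treatment_key(*t) for t in missing)
            raise DesignError(f"design is missing treatments: {names}")
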
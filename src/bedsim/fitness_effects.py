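"""Intended and unintended fitness effects of the drive systems.

Three suppression designs are modelled:

``ffBED``
    Female-fertility binary-expression drive: two unlinked drives (locus A
    transactivator, locus B effector).  Mothers carrying both components are
    sterilised (intended fecundity cost), scaled by the dominance degree.
``sBED``
    Seminal binary-expression drive: males carrying both components
    ("terminator" males) transfer a seminal toxin that kills the female after
    mating with probability terminator_efficiency × dominance multiplier.
``ffSD``
    Classic single suppression drive disrupting a haplosufficient female
    fertility gene at one locus (C).

Intended effects scale with a dominance multiplier over drive genotypes;
unintended reproductive/viability costs are dominant per-drive costs
(``(1-c)^k`` for ``k`` drive types carried); resistance-allele functionality
``rho`` sets the viability of resistance homozygotes (BED, target genes
essential for development) or their fecundity (ffSD, target gene essential
for female fertility only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .genetics import RR, Allele, Genotype, LocusGenotype

DESIGNS = ("ffBED", "sBED", "ffSD")

#: Drive-activity presets: ideal (perfect conversion, no unintended cost)
#: and reference (imperfect conversion, mild unintended costs).
ACTIVITY_PRESETS: dict[str, dict[str, float]] = {
    "IS": dict(
        homing_efficiency=1.0,
        resistance_formation=0.0,
        unintended_reproductive_cost=0.0,
        unintended_viability_cost=0.0,
    ),
    "RS": dict(
        homing_efficiency=0.9,
        resistance_formation=0.05,
        unintended_reproductive_cost=0.025,
        unintended_viability_cost=0.025,
    ),
}

#: Per-design defaults for the intended-effect parameters.
DESIGN_DEFAULTS: dict[str, dict[str, float]] = {
    "ffBED": dict(intended_fecundity_cost=1.0, terminator_efficiency=0.0, dominance_degree=0.6),
    "sBED": dict(intended_fecundity_cost=0.0, terminator_efficiency=0.95, dominance_degree=0.6),
    "ffSD": dict(intended_fecundity_cost=1.0, terminator_efficiency=0.0, dominance_degree=0.0),
}


@dataclass(frozen=True)
class DesignConfig:
    """All drive-system parameters for one design.

    Parameters
    ----------
    design:
        One of ``ffBED``, ``sBED``, ``ffSD``.
    intended_fecundity_cost:
        Relative fecundity reduction of mothers with full drive-system
        activity (AABB in BED designs, CC in ffSD).
    terminator_efficiency:
        Probability that mating with an AABB terminator male kills the
        female (sBED only).
    dominance_degree:
        Fraction of the full intended effect expressed by double
        heterozygotes (AaBb) or Cc heterozygotes.
    unintended_reproductive_cost, unintended_viability_cost:
        Dominant per-drive costs on fertility / male mating success and on
        egg viability.
    homing_efficiency, resistance_formation:
        Germline conversion probabilities in drive/wild-type heterozygotes.
    resistance_functionality:
        Relative functionality ``rho`` of resistance alleles: viability of
        resistance homozygote eggs in BED designs; preserved fecundity
        fraction of resistance-homozygous mothers in ffSD.
    ffsd_dr_rule:
        Fecundity rule for ffSD drive/resistance heterozygous mothers.
        ``"as_drive_homozygote"`` (default) treats them as having no
        functional target copy — both the drive and a nonfunctional
        resistance allele disrupt the fertility gene — so they pay the full
        intended cost like drive homozygotes.  ``"interpolate"`` instead
        places them between drive homozygotes and wild type linearly by the
        dominance degree (fully fertile when the disruption is recessive),
        which treats the dominance degree as acting per genotype rather than
        per disrupted allele.
    """

    design: str
    intended_fecundity_cost: float = 0.0
    terminator_efficiency: float = 0.0
    dominance_degree: float = 0.0
    unintended_reproductive_cost: float = 0.0
    unintended_viability_cost: float = 0.0
    homing_efficiency: float = 1.0
    resistance_formation: float = 0.0
    resistance_functionality: float = 0.0
    ffsd_dr_rule: str = "as_drive_homozygote"

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; expected one of {DESIGNS}")
        for name in (
            "intended_fecundity_cost",
            "terminator_efficiency",
            "dominance_degree",
            "unintended_reproductive_cost",
            "unintended_viability_cost",
            "homing_efficiency",
            "resistance_formation",
            "resistance_functionality",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.homing_efficiency + self.resistance_formation > 1.0 + 1e-12:
            raise ValueError(
                "homing_efficiency + resistance_formation must not exceed 1"
            )
        if self.ffsd_dr_rule not in ("interpolate", "as_drive_homozygote"):
            raise ValueError(f"unknown ffsd_dr_rule {self.ffsd_dr_rule!r}")

    @property
    def n_loci(self) -> int:
        return 1 if self.design == "ffSD" else 2

    @classmethod
    def preset(cls, design: str, activity: str = "RS", **overrides) -> "DesignConfig":
        """Build a config from a design's defaults and an activity preset.

        ``activity`` is ``"IS"`` (ideal system) or ``"RS"`` (reference
        system); keyword overrides take precedence over both.
        """
        if design not in DESIGNS:
            raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
        if activity not in ACTIVITY_PRESETS:
            raise ValueError(
                f"unknown activity preset {activity!r}; expected IS or RS"
            )
        params: dict = {}
        params.update(DESIGN_DEFAULTS[design])
        params.update(ACTIVITY_PRESETS[activity])
        params.update(overrides)
        return cls(design=design, **params)

    def with_(self, **overrides) -> "DesignConfig":
        return replace(self, **overrides)


def system_effect_multiplier(g: Genotype, dominance: float) -> float:
    """Fraction of the full intended drive-system effect expressed by ``g``.

    BED designs (two loci): 0 unless both loci carry a drive allele; the
    dominance degree for double heterozygotes; 1 for double homozygotes; and
    the midpoint ``(1 + Dd)/2`` when exactly one locus is drive-homozygous.
    Single-drive designs: 0 / dominance / 1 for 0 / 1 / 2 drive alleles.
    """
    dosages = [lg.drive_dosage for lg in g.loci]
    if g.n_loci == 1:
        d = dosages[0]
        return (0.0, dominance, 1.0)[d]
    dA, dB = dosages
    if dA == 0 or dB == 0:
        return 0.0
    if dA == 2 and dB == 2:
        return 1.0
    if dA == 1 and dB == 1:
        return dominance
    # one locus homozygous, the other heterozygous: intermediate effect
    return (1.0 + dominance) / 2.0


def terminator_kill_probability(male: Genotype, cfg: DesignConfig) -> float:
    """Probability that a female mated by ``male`` is killed by the seminal
    toxin; zero outside the sBED design."""
    if cfg.design != "sBED":
        return 0.0
    return cfg.terminator_efficiency * system_effect_multiplier(male, cfg.dominance_degree)


def intended_fecundity_factor(mother: Genotype, cfg: DesignConfig) -> float:
    """Multiplier on a mother's expected fecundity from the intended effect.

    ``1 - cost × dominance multiplier`` in the female-fertility designs
    (ffBED, ffSD); 1 in sBED, whose intended effect acts through
    mating-induced female death instead.
    """
    if cfg.design == "sBED":
        return 1.0
    return 1.0 - cfg.intended_fecundity_cost * system_effect_multiplier(
        mother, cfg.dominance_degree
    )


def unintended_reproductive_factor(g: Genotype, u: float) -> float:
    """Dominant per-drive unintended cost multiplier ``(1-u)^k`` where ``k``
    is the number of drive types carried.  Applies both to male mating
    success (sampling weight) and to mother fecundity."""
    if not (0.0 <= u <= 1.0):
        raise ValueError(f"unintended reproductive cost u={u} outside [0, 1]")
    return (1.0 - u) ** g.count_drive_types()


def egg_survival_probability(egg: Genotype, cfg: DesignConfig) -> float:
    """Probability that an egg survives to the larval stage.

    Combines the dominant per-drive unintended viability cost with
    resistance-allele lethality: in BED designs the target loci are essential
    for development, so eggs homozygous for resistance alleles at any locus
    survive with probability ``rho`` (0 by default: nonfunctional r2
    alleles).  In ffSD the target gene only affects female fertility, so
    ``rho`` does not act on viability.
    """
    p = (1.0 - cfg.unintended_viability_cost) ** egg.count_drive_types()
    if cfg.design != "ffSD" and any(lg == RR for lg in egg.loci):
        p *= cfg.resistance_functionality
    return p


def ffsd_fecundity_factor(mother: LocusGenotype, cfg: DesignConfig) -> float:
    """Fecundity multiplier of an ffSD mother from her target-locus genotype.

    Extends the intended fecundity cost to resistance alleles: resistance
    homozygotes keep a fraction ``rho`` of fecundity, resistance/wild-type
    heterozygotes are interpolated linearly by the dominance degree between
    the resistance homozygote and wild type, and drive/resistance
    heterozygotes follow ``cfg.ffsd_dr_rule`` (see :class:`DesignConfig`;
    by default they pay the full intended cost, having no functional copy
    of the fertility gene).
    """
    if cfg.design != "ffSD":
        raise ValueError("ffsd_fecundity_factor only applies to the ffSD design")
    cost = cfg.intended_fecundity_cost
    dd = cfg.dominance_degree
    rho = cfg.resistance_functionality
    nD = mother.count(Allele.D)
    nR = mother.count(Allele.R)
    if nD == 2:
        return 1.0 - cost
    if nD == 1 and nR == 1:
        if cfg.ffsd_dr_rule == "as_drive_homozygote":
            return 1.0 - cost
        return dd * (1.0 - cost) + (1.0 - dd)
    if nD == 1:  # drive/wild-type
        return 1.0 - cost * dd
    if nR == 2:
        return rho
    if nR == 1:  # resistance/wild-type
        return dd * rho + (1.0 - dd)
    return 1.0


def mother_fecundity_factor(mother: Genotype, cfg: DesignConfig) -> float:
    """Total multiplier on a mother's Poisson clutch mean.

    ffBED: intended cost × unintended reproductive cost.  ffSD: the
    target-locus fecundity table (which subsumes the intended cost and adds
    resistance-allele rules) × unintended cost.  sBED: unintended cost only.
    """
    u_factor = unintended_reproductive_factor(mother, cfg.unintended_reproductive_cost)
    if cfg.design == "ffSD":
        return ffsd_fecundity_factor(mother.loci[0], cfg) * u_factor
    return intended_fecundity_factor(mother, cfg) * u_factor
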
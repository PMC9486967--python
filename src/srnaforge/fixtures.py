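"""Deterministic synthetic inputs for the whole toolkit.

Everything the test suite and CLI smoke-run need is generated here
from a seeded RNG: an acrA-like annotated target mRNA (planted GAGG
Shine-Dalgarno, ATG at the 5' UTR end, no type IIS sites), Golden
Gate acceptor plasmids with the mCherry/ccdB counter-selection
cassette, and logistic plate-reader growth curves with optional
suppressor-mutant regrowth.  All generators are pure functions of
:class:`FixtureConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DesignError
from .goldengate import BBSI, OverhangScheme, TypeIISEnzyme, default_scheme, scan_type_iis
from .seed_design import TargetAnnotation
from .seqio import SeqRecordX, revcomp

MAX_REJECTION_ATTEMPTS = 10_000


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic inputs."""

    rng_seed: int = 42
    utr_len: int = 70          # SD "GAGG" planted at utr_len-8 .. utr_len-5
    cds_len: int = 180         # nt, divisible by 3; >= 160 leaves room for +152
    enzyme: TypeIISEnzyme = BBSI
    scheme: OverhangScheme = field(default_factory=default_scheme)
    backbone_len: int = 600
    cassette_len: int = 300
    # logistic growth defaults: carrying capacity, rate, inoculum, noise
    growth_k: float = 1.0      # OD600
    growth_r: float = 0.5      # 1/h
    growth_n0: float = 0.01    # OD600
    noise_sd: float = 0.01
    suppressor_delay: float = 12.0  # h until suppressor regrowth starts
    duration_h: float = 24.0
    n_timepoints: int = 97

    def __post_init__(self) -> None:
        if self.utr_len < 20 or self.cds_len < 160 or self.cds_len % 3:
            raise DesignError(
                "need utr_len >= 20 and cds_len >= 160 (divisible by 3) "
                "to host the default panel"
            )

    @property
    def sd_start(self) -> int:
        return self.utr_len - 8

    @property
    def sd_end(self) -> int:
        return self.utr_len - 5


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _clean_of_sites(seq: str, enz: TypeIISEnzyme) -> bool:
    return enz.recognition not in seq and revcomp(enz.recognition) not in seq


def _sample_clean(rng: np.random.Generator, n: int, enz: TypeIISEnzyme,
                  decorate=None) -> str:
    """Rejection-sample a random sequence free of enzyme sites."""
    for _ in range(MAX_REJECTION_ATTEMPTS):
        seq = _random_dna(rng, n)
        if decorate is not None:
            seq = decorate(seq)
        if _clean_of_sites(seq, enz):
            return seq
    raise DesignError("rejection sampling exhausted: cannot avoid enzyme sites")


def gen_target(cfg: FixtureConfig = FixtureConfig()) -> tuple[SeqRecordX, TargetAnnotation]:
    """An acrA-like annotated mRNA, deterministic under cfg.rng_seed."""
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.utr_len + cfg.cds_len

    def decorate(seq: str) -> str:
        s = list(seq)
        s[cfg.sd_start - 1 : cfg.sd_end] = "GAGG"
        s[cfg.utr_len : cfg.utr_len + 3] = "ATG"
        s[n - 3 : n] = "TAA"  # stop codon closes the CDS
        return "".join(s)

    seq = _sample_clean(rng, n, cfg.enzyme, decorate)
    mrna = SeqRecordX(id="target_mrna", sequence=seq, circular=False)
    ann = TargetAnnotation(
        mrna=mrna,
        sd_start=cfg.sd_start,
        sd_end=cfg.sd_end,
        start_codon=cfg.utr_len + 1,
        cds_end=n,
    )
    return mrna, ann


def gen_acceptor(cfg: FixtureConfig = FixtureConfig()) -> SeqRecordX:
    """Circular acceptor: backbone + counter-selection cassette.

    The cassette (mCherry and ccdB placeholder features) is flanked by
    two inward-pointing enzyme sites whose cuts expose the scheme's
    first and last fusion sites, so digestion yields a site-free
    backbone fragment and a cassette fragment carrying both sites.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    enz = cfg.enzyme
    junctions = cfg.scheme.junctions
    fill = "A" * enz.spacer

    backbone = _sample_clean(rng, cfg.backbone_len, enz)
    core = _sample_clean(rng, cfg.cassette_len, enz)

    # layout: [backbone] J0 fill rc(recognition) [core] recognition fill Jn
    left_arm = junctions[0] + fill + revcomp(enz.recognition)
    right_arm = enz.recognition + fill + junctions[-1]
    seq = backbone + left_arm + core + right_arm
    b0 = len(backbone)
    c0 = b0 + len(left_arm)
    third = cfg.cassette_len // 3
    features = [
        ("ori", 10, 110, 1),
        ("nptII", 150, 500, 1),
        ("mCherry", c0 + 1, c0 + third, 1),
        ("ccdB", c0 + third + 10, c0 + 2 * third, 1),
    ]
    rec = SeqRecordX(id="acceptor", sequence=seq, circular=True, features=features)
    sites = scan_type_iis(rec, enz)
    if len(sites) != 2:
        raise DesignError(f"acceptor construction produced {len(sites)} sites, expected 2")
    return rec


def gen_multi_acceptor(cfg: FixtureConfig, n_slots: int) -> SeqRecordX:
    """Acceptor whose cassette drop-out spans ``n_slots`` insert slots."""
    scheme = default_scheme(n_slots)
    return gen_acceptor(replace(cfg, scheme=scheme))


@dataclass(frozen=True)
class GrowthCondition:
    """What a simulated well experiences."""

    strain: str = "control"
    oxacillin: float = 0.0
    induced: bool = False
    k_scale: float = 1.0       # multiplies the carrying capacity
    r_scale: float = 1.0       # multiplies the growth rate
    suppressor: bool = False   # delayed second logistic (regrowth)


def _logistic(t: np.ndarray, k: float, r: float, n0: float) -> np.ndarray:
    return k / (1.0 + ((k - n0) / n0) * np.exp(-r * t))


def gen_growth(cfg: FixtureConfig, condition: GrowthCondition = GrowthCondition()):
    """A simulated plate-reader OD600 trajectory.

    Logistic growth plus Gaussian noise; in suppressor mode a delayed
    second logistic overtakes the (inhibited) primary population, so
    the endpoint OD looks healthy while the early-time AUC stays low.
    """
    from .assay import GrowthCurve  # local import avoids a cycle

    strain_tag = sum(ord(c) * (i + 1) for i, c in enumerate(condition.strain))
    rng = np.random.default_rng(
        (cfg.rng_seed * 1_000_003 + strain_tag % 65_536
         + int(condition.oxacillin * 10) + (1 if condition.induced else 0)) % (2**31)
    )
    t = np.linspace(0.0, cfg.duration_h, cfg.n_timepoints)
    k = cfg.growth_k * condition.k_scale
    od = _logistic(t, max(k, 1e-6), cfg.growth_r * condition.r_scale, cfg.growth_n0)
    if condition.suppressor:
        t2 = np.clip(t - cfg.suppressor_delay, 0.0, None)
        regrow = _logistic(t2, cfg.growth_k, cfg.growth_r * 1.5, cfg.growth_n0)
        regrow[t <= cfg.suppressor_delay] = 0.0
        od = np.maximum(od, regrow)
    if cfg.noise_sd > 0:
        od = od + rng.normal(0.0, cfg.noise_sd, size=od.shape)
    od = np.clip(od, 0.0, None)
    return GrowthCurve(
        times=t,
        od=od,
        strain=condition.strain,
        oxacillin=condition.oxacillin,
        induced=condition.induced,
    )


def gen_plate(cfg: FixtureConfig = FixtureConfig()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A small synthetic screen: long-format plate table + well map.

    Two strains at two oxacillin levels, three replicates each arm:
    a control whose growth the inducer mildly promotes, and an
    effective sRNA strain whose induced arm is growth-inhibited under
    oxacillin.
    """
    rows, wellmap = [], []
    widx = 0
    for strain, eff in (("control", 1.0), ("sRNA-s8", 0.35)):
        for oxa in (0.0, 100.0):
            for induced in (False, True):
                for rep in range(3):
                    widx += 1
                    well = f"{chr(ord('A') + widx // 12)}{widx % 12 + 1}"
                    if induced:
                        k_scale = 1.1 if eff == 1.0 or oxa == 0.0 else eff
                    else:
                        k_scale = 1.0
                    curve = gen_growth(
                        replace(cfg, rng_seed=cfg.rng_seed + rep),
                        GrowthCondition(
                            strain=strain, oxacillin=oxa, induced=induced, k_scale=k_scale
                        ),
                    )
                    wellmap.append(
                        {
                            "well": well,
                            "strain": strain,
                            "oxacillin_ug_ml": oxa,
                            "arabinose": induced,
                        }
                    )
                    for t, od in zip(curve.times, curve.od):
                        rows.append({"time_h": round(float(t), 4), "well": well,
                                     "od600": round(float(od), 5)})
    return pd.DataFrame(rows), pd.DataFrame(wellmap)
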
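"""Synthetic inputs with the statistical structure the pipeline assumes.

Every table the analysis consumes can be generated here with planted,
recoverable ground truth:

* a miRNA catalog in which a configurable number of family pairs is
  constructed to overlap extensively (a partner seed is the base seed
  shifted by 1-2 nt), while rejection sampling guarantees that no other
  pair overlaps extensively for any site type;
* a site table with planted seed-overlap and neighborhood cotarget
  geometry (all other placements isolated by >100 nt);
* species-presence rows drawn from a two-class conservation-depth
  mixture, nested along a ladder-shaped ultrametric species tree whose
  branch lengths keep the BLS-cutoff call consistent with the planted
  species counts;
* an expression table following an additive per-site repression model
  with Gaussian noise and an optional cooperativity term for the
  double-miRNA condition;
* haploinsufficiency probabilities with a class-conditional Beta shift.

One ``rng_seed`` fixes every emitted file byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .seed_model import SITE_LENGTHS, ConservationGroup, MirnaRecord, site_match
from .overlap_stats import EXTENSIVE_K, is_extensive, max_overlap

_CONSERVABLE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
_RNA = "ACGU"


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults matching the
    analysis conditions (84-species panel, 62-species depth threshold,
    65/35 shallow/deep mixture, 15-100 nt neighborhood distances,
    additive log2 repression with the 8mer > 7mer > 6mer hierarchy)."""

    rng_seed: int = 0
    # catalog
    n_mirnas: int = 30
    n_planted_extensive_pairs: int = 5
    p_cluster_extensive: float = 0.7
    p_cluster_other: float = 0.2
    p_multilocus_extensive: float = 0.6
    p_multilocus_other: float = 0.15
    # sites
    n_genes: int = 2000
    n_sites: int = 4000
    p_conserved: float = 0.5
    frac_overlap_cotargets: float = 0.10
    frac_neighborhood_cotargets: float = 0.10
    neighborhood_range: tuple[int, int] = (15, 100)
    # conservation
    panel_size: int = 84
    species_threshold: int = 62
    w_shallow: float = 0.65
    shallow_range: tuple[int, int] = (20, 61)
    deep_range: tuple[int, int] = (62, 84)
    nonconserved_range: tuple[int, int] = (1, 19)
    # expression
    beta: dict = field(
        default_factory=lambda: {
            "8mer": -0.6, "7mer-m8": -0.4, "7mer-A1": -0.3, "6mer": -0.12
        }
    )
    sigma: float = 0.15
    delta: float = 0.0
    fdr_threshold: float = 0.05
    # haploinsufficiency
    hi_base_mean: float = 0.35
    hi_shift: float = 0.2
    hi_concentration: float = 8.0

    def __post_init__(self) -> None:
        if self.n_mirnas < 2:
            raise ValueError("n_mirnas must be >= 2")
        max_pairs = self.n_mirnas * (self.n_mirnas - 1) // 2
        if self.n_planted_extensive_pairs > max_pairs:
            raise ValueError(
                f"cannot plant {self.n_planted_extensive_pairs} pairs among "
                f"{self.n_mirnas} miRNAs"
            )
        if 2 * self.n_planted_extensive_pairs > self.n_mirnas:
            raise ValueError("planted pairs need 2 dedicated miRNAs each")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        b = self.beta
        if not (b["8mer"] < b["7mer-m8"] <= b["7mer-A1"] < b["6mer"] < 0):
            raise ValueError(
                "site-type effects must satisfy 8mer < 7mer-m8 <= 7mer-A1 "
                "< 6mer < 0 (log2 scale)"
            )
        for name in ("p_conserved", "frac_overlap_cotargets",
                     "frac_neighborhood_cotargets", "w_shallow",
                     "p_cluster_extensive", "p_cluster_other",
                     "p_multilocus_extensive", "p_multilocus_other"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("neighborhood_range", "shallow_range", "deep_range",
                    "nonconserved_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        for key in ("neighborhood_range", "shallow_range", "deep_range",
                    "nonconserved_range"):
            raw[key] = list(raw[key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _rngs(cfg: SimConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(cfg.rng_seed).spawn(n)]


def planted_pair_families(cfg: SimConfig) -> list[tuple[str, str]]:
    """Family-id pairs the catalog generator plants as extensive overlaps."""
    return [
        (f"fam-{2 * i:03d}", f"fam-{2 * i + 1:03d}")
        for i in range(cfg.n_planted_extensive_pairs)
    ]


def _random_seed(rng: np.random.Generator) -> str:
    return "".join(_RNA[i] for i in rng.integers(0, 4, size=7))


def _seeds_conflict(s1: str, s2: str) -> bool:
    """True when two seeds are identical or any site type overlaps extensively."""
    if s1 == s2:
        return True
    return any(
        is_extensive(site_match(s1, st).sequence, site_match(s2, st).sequence, st)
        for st in ("8mer", "7mer-m8", "7mer-A1")
    )


def _shifted_partner(base: str, shift: int, rng: np.random.Generator) -> str:
    """Seed whose 7mer-m8 site overlaps the base's by 7 - shift nt."""
    tail = "".join(_RNA[i] for i in rng.integers(0, 4, size=shift))
    return base[shift:] + tail


def simulate_mirna_catalog(cfg: SimConfig) -> list[MirnaRecord]:
    """Catalog with planted extensive pairs and clean non-planted seeds.

    The first ``2 * n_planted_extensive_pairs`` families form the planted
    pairs (partner = base seed shifted by 1 or 2 nt, so the 7mer-m8
    maximum overlap is 6 or 5 nt).  Every other seed is rejection-sampled
    until it overlaps no accepted seed extensively for any site type, so
    the planted pairs are exactly the extensive pairs of the catalog.
    Planted families receive cluster / multi-locus annotations with
    elevated probability.
    """
    rng = _rngs(cfg, 1)[0]
    seeds: list[str] = []
    planted = set()
    for i in range(cfg.n_planted_extensive_pairs):
        for _ in range(10_000):
            base = _random_seed(rng)
            shift = int(rng.integers(1, 3))
            partner = _shifted_partner(base, shift, rng)
            if partner == base:
                continue
            k, _ = max_overlap(
                site_match(base, "7mer-m8").sequence,
                site_match(partner, "7mer-m8").sequence,
            )
            if k not in EXTENSIVE_K["7mer-m8"]:
                continue
            if any(_seeds_conflict(base, s) or _seeds_conflict(partner, s)
                   for s in seeds):
                continue
            seeds += [base, partner]
            planted |= {len(seeds) - 2, len(seeds) - 1}
            break
        else:
            raise RuntimeError("could not plant extensive pair")
    while len(seeds) < cfg.n_mirnas:
        for _ in range(10_000):
            cand = _random_seed(rng)
            if not any(_seeds_conflict(cand, s) for s in seeds):
                seeds.append(cand)
                break
        else:
            raise RuntimeError("could not sample a clean random seed")

    records = []
    for i, seed in enumerate(seeds):
        nt1 = _RNA[rng.integers(0, 4)]
        tail = "".join(_RNA[j] for j in rng.integers(0, 4, size=14))
        mature = nt1 + seed + tail
        is_planted = i in planted
        p_cl = cfg.p_cluster_extensive if is_planted else cfg.p_cluster_other
        p_ml = cfg.p_multilocus_extensive if is_planted else cfg.p_multilocus_other
        records.append(
            MirnaRecord(
                mirna_id=f"mir-{i:03d}",
                mature_seq=mature,
                family_id=f"fam-{i:03d}",
                conservation_group=ConservationGroup.BROADLY_CONSERVED,
                mirbase_accession=f"MIMAT{i:07d}",
                in_cluster=bool(rng.random() < p_cl),
                n_genomic_loci=2 if rng.random() < p_ml else 1,
            )
        )
    return records


# ---------------------------------------------------------------------------
# species panel and ladder tree

def species_panel(panel_size: int = 84) -> list[str]:
    """Ordered synthetic panel: human first, then by divergence."""
    return ["human"] + [f"sp{i:03d}" for i in range(1, panel_size)]


def _divergence_times(panel_size: int) -> np.ndarray:
    """Divergence time of species i from the human lineage (i = 1..n-1).

    A shallow ramp for the first 18 species, a long jump before the 19th,
    then a slow ramp: planted non-conserved sites (<= 19 species) stay
    below every BLS cutoff while planted conserved sites (>= 20 species)
    clear all of them.
    """
    t = np.empty(panel_size)          # t[0] unused (human)
    t[0] = np.nan
    for i in range(1, panel_size):
        if i <= 18:
            t[i] = 0.005 * i
        else:
            t[i] = 1.5 + 0.01 * (i - 19)
    return t


def ladder_tree_newick(panel_size: int = 84) -> str:
    """Ultrametric pectinate species tree matching the nested presence model."""
    panel = species_panel(panel_size)
    t = _divergence_times(panel_size)
    node = f"({panel[0]}:{t[1]:.6f},{panel[1]}:{t[1]:.6f})"
    for i in range(2, panel_size):
        node = f"({node}:{t[i] - t[i - 1]:.6f},{panel[i]}:{t[i]:.6f})"
    return node + ";"


def bls_by_species_count(panel_size: int = 84) -> np.ndarray:
    """Closed-form BLS of the nested presence prefix, indexed by n_species.

    A site present in the first ``n`` panel species spans the ladder up
    to divergence ``t[n-1]``: the spanning subtree contains every pendant
    edge of the present species plus the spine from the first to the
    deepest split.
    """
    t = _divergence_times(panel_size)
    out = np.zeros(panel_size + 1)
    csum = 0.0
    for m in range(1, panel_size):
        csum += t[m]
        # pendant edges (incl. human's t[1]) plus the spine t[m] - t[1]
        out[m + 1] = csum + t[m]
    return out


# ---------------------------------------------------------------------------
# sites, conservation, cotarget geometry

@dataclass
class SimulatedSites:
    """Site table plus the conservation side-inputs it references."""

    sites: pd.DataFrame
    presence: pd.DataFrame
    tree_newick: str
    panel: list[str]


def _draw_depth(cfg: SimConfig, conserved: bool, rng) -> tuple[str, int]:
    if not conserved:
        lo, hi = cfg.nonconserved_range
        return "nonconserved", int(rng.integers(lo, hi + 1))
    if rng.random() < cfg.w_shallow:
        lo, hi = cfg.shallow_range
        return "shallow", int(rng.integers(lo, hi + 1))
    lo, hi = cfg.deep_range
    return "deep", int(rng.integers(lo, hi + 1))


def simulate_sites_and_conservation(
    cfg: SimConfig, records: list[MirnaRecord]
) -> SimulatedSites:
    """Sites with planted cotarget geometry and two-class conservation.

    Conserved-site counts are allocated deterministically: a fraction
    ``frac_overlap_cotargets`` of conserved sites form seed-overlap pairs
    of planted extensive families (intervals overlapping by the pair's
    true maximum overlap), ``frac_neighborhood_cotargets`` form
    neighborhood pairs (seed starts 15-100 nt apart), and the rest are
    isolated (>100 nt from any other site).  Non-conserved sites are all
    isolated.  Presence vectors are nested prefixes of the panel.
    """
    rng = _rngs(cfg, 2)[1]
    seeds_by_family = {r.family_id: r.seed for r in records}
    families = sorted(seeds_by_family)
    pairs = planted_pair_families(cfg)

    n_conserved = round(cfg.n_sites * cfg.p_conserved)
    n_ov_pairs = round(cfg.frac_overlap_cotargets * n_conserved / 2)
    n_nb_pairs = round(cfg.frac_neighborhood_cotargets * n_conserved / 2)
    n_single_cons = n_conserved - 2 * (n_ov_pairs + n_nb_pairs)
    if n_single_cons < 0:
        raise ValueError("cotarget fractions exceed the conserved budget")
    n_noncons = cfg.n_sites - n_conserved

    # placement units: (mode, [(family, site_type, rel_start, conserved)])
    units = []
    for _ in range(n_ov_pairs):
        fa, fb = pairs[rng.integers(0, len(pairs))]
        k, _off = max_overlap(
            site_match(seeds_by_family[fa], "7mer-m8").sequence,
            site_match(seeds_by_family[fb], "7mer-m8").sequence,
        )
        off = SITE_LENGTHS["7mer-m8"] - k
        units.append(("overlap", [(fa, "7mer-m8", 0, True),
                                  (fb, "7mer-m8", off, True)]))
    lo, hi = cfg.neighborhood_range
    for _ in range(n_nb_pairs):
        fa = families[rng.integers(0, len(families))]
        fb = (fa if rng.random() < 0.5
              else families[rng.integers(0, len(families))])
        st_a = _CONSERVABLE_TYPES[rng.integers(0, 3)]
        st_b = _CONSERVABLE_TYPES[rng.integers(0, 3)]
        d = int(rng.integers(lo, hi + 1))
        units.append(("neighborhood", [(fa, st_a, 0, True),
                                       (fb, st_b, d, True)]))
    for _ in range(n_single_cons):
        fam = families[rng.integers(0, len(families))]
        st = _CONSERVABLE_TYPES[rng.integers(0, 3)]
        units.append(("single", [(fam, st, 0, True)]))
    for _ in range(n_noncons):
        fam = families[rng.integers(0, len(families))]
        st = ("8mer", "7mer-m8", "7mer-A1", "6mer")[rng.integers(0, 4)]
        units.append(("single", [(fam, st, 0, False)]))

    order = rng.permutation(len(units))
    cursors = np.zeros(cfg.n_genes, dtype=int)
    bls_table = bls_by_species_count(cfg.panel_size)
    panel = species_panel(cfg.panel_size)

    rows, presence_rows, presence_ids = [], [], []
    sid = 0
    for u in order:
        mode, members = units[u]
        gene = int(rng.integers(0, cfg.n_genes))
        base = int(cursors[gene]) + 110 + int(rng.integers(0, 40))
        unit_end = base
        for fam, st, rel, conserved in members:
            L = SITE_LENGTHS[st]
            start = base + rel
            end = start + L
            unit_end = max(unit_end, end)
            depth, n_sp = _draw_depth(cfg, conserved, rng)
            rows.append(
                {
                    "site_id": f"site{sid:06d}",
                    "gene_id": f"gene{gene:05d}",
                    "utr_id": f"gene{gene:05d}.utr1",
                    "start": start,
                    "end": end,
                    "family_id": fam,
                    "site_type": st,
                    "conserved": conserved,
                    "bls": round(float(bls_table[n_sp]), 6),
                    "n_species": n_sp,
                    "depth_class": depth,
                    "planted_cotarget": mode,
                }
            )
            vec = np.zeros(cfg.panel_size, dtype=int)
            vec[:n_sp] = 1
            presence_rows.append(vec)
            presence_ids.append(f"site{sid:06d}")
            sid += 1
        cursors[gene] = unit_end
    sites = pd.DataFrame(rows).sort_values(
        ["gene_id", "start"], kind="stable"
    ).reset_index(drop=True)
    presence = pd.DataFrame(
        np.vstack(presence_rows), index=pd.Index(presence_ids, name="site_id"),
        columns=panel,
    ).loc[sites["site_id"]]
    return SimulatedSites(
        sites=sites,
        presence=presence,
        tree_newick=ladder_tree_newick(cfg.panel_size),
        panel=panel,
    )


# ---------------------------------------------------------------------------
# expression and haploinsufficiency

def simulate_expression(
    cfg: SimConfig,
    sites: pd.DataFrame,
    fam_a: str | None = None,
    fam_b: str | None = None,
) -> pd.DataFrame:
    """Additive per-site repression model for two focal miRNAs.

    ``log2fc_mir_x = sum(beta[site_type] over x's sites) + N(0, sigma)``
    per gene; the double condition is the sum of the two noisy singles
    plus ``delta`` for genes carrying sites of both families plus fresh
    noise.  FDR columns are BH-adjusted two-sided z-test p-values using
    the known noise scale.  All ``n_genes`` genes are included; genes
    without sites form the background.
    """
    if fam_a is None or fam_b is None:
        fam_a, fam_b = planted_pair_families(cfg)[0]
    rng = _rngs(cfg, 3)[2]
    genes = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    beta = cfg.beta
    signal = {fam: np.zeros(cfg.n_genes) for fam in (fam_a, fam_b)}
    gene_index = {g: i for i, g in enumerate(genes)}
    for row in sites.itertuples(index=False):
        if row.family_id in signal:
            signal[row.family_id][gene_index[row.gene_id]] += beta[row.site_type]
    has_both = (signal[fam_a] < 0) & (signal[fam_b] < 0)
    fc_a = signal[fam_a] + rng.normal(0, cfg.sigma, cfg.n_genes)
    fc_b = signal[fam_b] + rng.normal(0, cfg.sigma, cfg.n_genes)
    fc_both = (
        fc_a + fc_b + cfg.delta * has_both
        + rng.normal(0, cfg.sigma, cfg.n_genes)
    )
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for cond, fc, scale in (
        ("mir_a", fc_a, cfg.sigma),
        ("mir_b", fc_b, cfg.sigma),
        ("both", fc_both, cfg.sigma * np.sqrt(3.0)),
    ):
        p = 2 * stats.norm.sf(np.abs(fc) / scale)
        out[f"log2fc_{cond}"] = np.round(fc, 6)
        out[f"fdr_{cond}"] = np.round(multipletests(p, method="fdr_bh")[1], 8)
    out["mean_cpm"] = np.round(rng.lognormal(np.log(50), 1.5, cfg.n_genes), 3)
    return out


def simulate_hi(
    cfg: SimConfig, genes: list[str], boosted_genes: set[str]
) -> pd.Series:
    """Beta-distributed haploinsufficiency probabilities per gene.

    ``boosted_genes`` (e.g. deep-class or conserved-overlap targets) draw
    from a Beta with mean shifted up by ``hi_shift``; all values lie in
    [0, 1] by construction.
    """
    rng = _rngs(cfg, 4)[3]
    nu = cfg.hi_concentration
    vals = np.empty(len(genes))
    for i, g in enumerate(genes):
        mu = cfg.hi_base_mean + (cfg.hi_shift if g in boosted_genes else 0.0)
        mu = min(max(mu, 1e-3), 1 - 1e-3)
        vals[i] = rng.beta(mu * nu, (1 - mu) * nu)
    return pd.Series(np.round(vals, 6), index=pd.Index(genes, name="gene_id"),
                     name="p_hi")


def simulate_paired_repression(
    n: int,
    delta: float,
    sigma: float,
    rng: np.random.Generator,
    mu_a: float = -0.5,
    mu_b: float = -0.3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired single/single/double log2FC replicates for additivity tests.

    ``fc_double = fc_a + fc_b + delta + noise``; ``delta = 0`` is the
    purely additive regime.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    fc_a = mu_a + rng.normal(0, sigma, n)
    fc_b = mu_b + rng.normal(0, sigma, n)
    fc_double = fc_a + fc_b + delta + rng.normal(0, sigma, n)
    return fc_a, fc_b, fc_double


def simulate_gene_sets(
    cfg: SimConfig, sites: pd.DataFrame, n_random_sets: int = 10
) -> dict[str, set[str]]:
    """GMT-style gene sets: one enriched in planted overlap-cotarget genes
    plus random decoys drawn from all genes."""
    rng = _rngs(cfg, 5)[4]
    genes = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    overlap_genes = sorted(
        set(sites.loc[sites["planted_cotarget"] == "overlap", "gene_id"])
    )
    sets: dict[str, set[str]] = {}
    if overlap_genes:
        take = [g for g in overlap_genes if rng.random() < 0.8]
        pad = [genes[i] for i in rng.integers(0, len(genes), size=10)]
        sets["PLANTED_OVERLAP_PATHWAY"] = set(take) | set(pad)
    for j in range(n_random_sets):
        size = int(rng.integers(20, 80))
        members = {genes[i] for i in rng.integers(0, len(genes), size=size)}
        sets[f"RANDOM_SET_{j:02d}"] = members
    return sets
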
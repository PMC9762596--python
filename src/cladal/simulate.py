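"""Synthetic data emulating the two-study, two-age, two-timepoint design.

The generator reproduces the statistical structure the cladal analysis
assumes: 80 mice (two studies of 40 — supplementation ZAM1: ZA vs ZS,
deficiency ZAM2: ZA vs ZD — each with 10 young and 10 old mice per
diet arm), fecal samples at weeks 0 and 6, NB-distributed ASV counts
with a per-host random intercept, library sizes log-normal around
130,000 reads, and an LPS-induced IL-6 covariate that rises with age
and with zinc deficiency.

Planted effects are applied multiplicatively to every member tip of a
target clade, so the hierarchical consistency of the clade matrix is
preserved by construction, and a truth table records each effect for
recovery testing.  All outputs are reproducible bit-for-bit from the
design's master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from skbio import TreeNode

from .clades import clade_id_for, enumerate_clades
from .tables import AsvTable, SampleMetadata
from .tree import PhyloTree, ValidationError


@dataclass(frozen=True)
class IL6Model:
    """Week-6 whole-blood LPS-induced IL-6 (pg/ml) generator.

    IL-6 = baseline + age_increment (old) + deficiency_increment (ZD)
           + Normal(0, noise_sd), truncated at 0; missing at week 0.
    """
    baseline: float = 40.0
    age_increment: float = 60.0
    deficiency_increment: float = 40.0
    noise_sd: float = 25.0


@dataclass(frozen=True)
class PlantedEffect:
    """A multiplicative abundance effect on one clade's member tips.

    ``covariate`` is ``"age"`` (applies to old samples), ``"diet"``
    (applies to the zinc-modified arm of one age x study family), or
    ``"il6"`` (per-unit slope on IL-6, week-6 samples of one age
    group).  For age and diet, ``log_fc`` is the log fold-change; for
    il6 it is the slope per pg/ml.
    """
    clade_id: str
    tips: frozenset
    covariate: str
    log_fc: float
    age: str | None = None
    study: str | None = None


@dataclass(frozen=True)
class SimulationDesign:
    """Study conditions for the synthetic generator."""
    n_tips: int = 361
    hosts_per_cell: int = 10          # per age x diet x study cell
    theta: float = 2.0                # NB dispersion
    sigma_b: float = 0.5              # host random-intercept SD (log scale)
    baseline_log_sd: float = 2.3      # ~4 orders of magnitude dynamic range
    mean_depth: float = 130_000.0     # mean library size before rarefaction
    depth_log_sd: float = 0.25
    il6: IL6Model = field(default_factory=IL6Model)
    effects: tuple = ()
    target_mass_cap: float = 0.002    # planted clades are rare taxa: cap on a
                                      # planted clade's baseline rel. abundance
    seed: int = 0


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(5)
    names = ("tree", "meta", "baseline", "targets", "counts")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_tree(n_tips: int, seed) -> PhyloTree:
    """Random fully bifurcating rooted tree, tips ASV1..ASVn.

    Built by repeated random joins with exponential branch lengths
    (mean 0.1 substitutions/site); reproducible by seed.
    """
    if n_tips < 2:
        raise ValidationError("n_tips must be at least 2")
    rng = np.random.default_rng(seed)
    nodes = []
    for i in range(n_tips):
        t = TreeNode(name=f"ASV{i + 1}")
        t.length = float(rng.exponential(0.1))
        nodes.append(t)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a = nodes.pop(j)
        b = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.1)))
        parent.extend([b, a])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return PhyloTree(root, rooted=True, validate=False)


def simulate_metadata(design: SimulationDesign, seed=None) -> SampleMetadata:
    """Hosts and samples for the two-study design, with week-6 IL-6."""
    rng = np.random.default_rng(seed) if seed is not None \
        else _streams(design.seed)["meta"]
    il6m = design.il6
    rows = []
    for study, treat in (("ZAM1", "ZS"), ("ZAM2", "ZD")):
        for age in ("young", "old"):
            for diet in ("ZA", treat):
                for h in range(design.hosts_per_cell):
                    host = f"{study}_{age}_{diet}_h{h + 1:02d}"
                    il6 = (il6m.baseline
                           + (il6m.age_increment if age == "old" else 0.0)
                           + (il6m.deficiency_increment if diet == "ZD" else 0.0)
                           + rng.normal(0.0, il6m.noise_sd))
                    il6 = max(il6, 0.0)
                    for tp in ("wk0", "wk6"):
                        rows.append({
                            "sample_id": f"{host}_{tp}", "host_id": host,
                            "age": age, "diet": diet, "study": study,
                            "timepoint": tp,
                            "il6": il6 if tp == "wk6" else np.nan,
                        })
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


def _draw_baselines(design: SimulationDesign, tree: PhyloTree) -> pd.Series:
    """Per-ASV expected relative abundance, log-normal across tips.

    Deterministic given the design seed and tip count, so that target
    selection and count generation agree on the abundance structure.
    """
    rng = _streams(design.seed)["baseline"]
    tips = tree.tip_names
    raw = np.exp(rng.normal(0.0, design.baseline_log_sd, size=len(tips)))
    return pd.Series(raw / raw.sum(), index=tips, name="rel_abundance")


DIET_FAMILIES = (("young", "ZAM1", "ZS"), ("old", "ZAM1", "ZS"),
                 ("young", "ZAM2", "ZD"), ("old", "ZAM2", "ZD"))


def choose_default_effects(tree: PhyloTree, design: SimulationDesign,
                           n_per_battery: int = 5, log_fc: float = 1.5,
                           il6_slope_scale: float = 100.0) -> tuple:
    """Plant ``n_per_battery`` effects per battery on small, rare clades.

    Targets are clades of 2-4 tips drawn from the lower half of the
    baseline-abundance distribution, with disjoint tip sets, so that
    the planted fold-changes perturb total composition only weakly.
    Diet effects rotate over the four age x study families; IL-6
    effects alternate age groups with slope ``log_fc / il6_slope_scale``
    per pg/ml (i.e. the stated fold-change per 100 pg/ml).
    """
    rng = _streams(design.seed)["targets"]
    base = _draw_baselines(design, tree)
    clades = enumerate_clades(tree)
    small = [(cid, mem) for cid, mem in clades if 2 <= len(mem) <= 4]
    if not small:
        raise ValidationError("tree has no clades of 2-4 tips to plant on")
    mass = {cid: base[list(mem)].sum() for cid, mem in small}
    cutoff = np.median(list(mass.values()))
    rng.shuffle(small)
    # prefer rare clades (weak compositional spillover); fall back to the
    # rest of the small-clade pool only if the rare pool runs short
    eligible = sorted(small, key=lambda cm: mass[cm[0]] > cutoff)
    used: set = set()
    picked = []
    for cid, mem in eligible:
        if mem & used:
            continue
        picked.append((cid, mem))
        used |= mem
        if len(picked) >= 3 * n_per_battery:
            break
    if len(picked) < 3 * n_per_battery:
        raise ValidationError(
            f"only {len(picked)} disjoint small clades available; "
            f"need {3 * n_per_battery}"
        )
    effects = []
    for k in range(n_per_battery):
        cid, mem = picked[k]
        effects.append(PlantedEffect(cid, mem, "age", log_fc))
    for k in range(n_per_battery):
        cid, mem = picked[n_per_battery + k]
        age, study, _ = DIET_FAMILIES[k % 4]
        effects.append(PlantedEffect(cid, mem, "diet", log_fc,
                                     age=age, study=study))
    for k in range(n_per_battery):
        cid, mem = picked[2 * n_per_battery + k]
        age = ("young", "old")[k % 2]
        effects.append(PlantedEffect(cid, mem, "il6",
                                     log_fc / il6_slope_scale, age=age))
    return tuple(effects)


def simulate_counts(design: SimulationDesign, tree: PhyloTree,
                    meta: SampleMetadata) -> tuple[AsvTable, pd.DataFrame]:
    """NB counts per sample x tip, plus the planted-effect truth table.

    For sample s of host h and tip t:

        log mu = log(mean_depth * p_t) + sum(active planted effects)
                 + b_h + o_s,   b_h ~ N(0, sigma_b^2), o_s ~ N(0, depth_log_sd^2)
        y ~ NB(mu, theta)

    Clade effects multiply every member tip, so clade sums inherit the
    planted fold-change exactly.
    """
    tips = tree.tip_names
    tip_index = {t: i for i, t in enumerate(tips)}
    known = enumerate_clades(tree)
    known_ids = {cid for cid, _ in known}
    for eff in design.effects:
        if eff.clade_id not in known_ids:
            raise ValidationError(f"planted effect on unknown clade {eff.clade_id}")

    base = _draw_baselines(design, tree)
    # Planted targets emulate rare-but-consistently-present taxa: each
    # planted clade's baseline mass is clamped into [cap/2, cap] and spread
    # equally over its member tips, so the planted fold-changes leave total
    # composition (and hence every unplanted clade's rarefied abundance)
    # essentially unchanged while every planted tip stays above the
    # prevalence floor.
    if design.effects and design.target_mass_cap:
        cap = design.target_mass_cap
        vals = base.to_numpy().copy()
        tidx = {t: i for i, t in enumerate(base.index)}
        for eff in design.effects:
            cols = [tidx[t] for t in eff.tips]
            m = float(np.clip(vals[cols].sum(), cap / 2.0, cap))
            vals[cols] = m / len(cols)
        base = pd.Series(vals / vals.sum(), index=base.index)
    rng = _streams(design.seed)["counts"]
    md = meta.data
    samples = list(md.index)
    n_s, n_t = len(samples), len(tips)

    hosts = md["host_id"].unique()
    b_h = pd.Series(rng.normal(0.0, design.sigma_b, size=len(hosts)), index=hosts)
    o_s = rng.normal(0.0, design.depth_log_sd, size=n_s)

    log_mu = np.tile(np.log(design.mean_depth * base.to_numpy()), (n_s, 1))
    log_mu += b_h[md["host_id"]].to_numpy()[:, None]
    log_mu += o_s[:, None]

    truth_rows = []
    for eff in design.effects:
        cols = [tip_index[t] for t in eff.tips]
        if eff.covariate == "age":
            active = (md["age"] == "old").to_numpy(dtype=float)
        elif eff.covariate == "diet":
            treat = {"ZAM1": "ZS", "ZAM2": "ZD"}[eff.study]
            active = ((md["age"] == eff.age) & (md["study"] == eff.study)
                      & (md["diet"] == treat)).to_numpy(dtype=float)
        elif eff.covariate == "il6":
            il6 = md["il6"].fillna(0.0).to_numpy()
            in_age = (md["age"] == eff.age).to_numpy(dtype=float) \
                if eff.age else np.ones(n_s)
            active = il6 * in_age
        else:
            raise ValidationError(f"unknown covariate {eff.covariate!r}")
        log_mu[np.ix_(active != 0, cols)] += (eff.log_fc *
                                              active[active != 0][:, None])
        truth_rows.append({
            "clade_id": eff.clade_id, "covariate": eff.covariate,
            "log_fc": eff.log_fc, "age": eff.age or "", "study": eff.study or "",
            "n_tips": len(eff.tips), "member_tips": ",".join(sorted(eff.tips)),
        })

    mu = np.exp(np.clip(log_mu, -30.0, 30.0))
    theta = design.theta
    y = rng.negative_binomial(theta, theta / (theta + mu), size=(n_s, n_t))
    table = AsvTable(pd.DataFrame(y, index=samples, columns=tips))
    truth = pd.DataFrame(
        truth_rows, columns=["clade_id", "covariate", "log_fc", "age",
                             "study", "n_tips", "member_tips"],
    )
    return table, truth


def simulate_taxonomy(tree: PhyloTree, seed=None,
                      unknown_genus_frac: float = 0.3) -> "TaxonomyTable":
    """Tree-consistent taxonomy for simulated tips.

    Ranks are defined by cutting the tree into progressively finer
    monophyletic groups (phylum coarsest, genus finest), so consensus
    labels behave like real lineages.  A fraction of genera is set to
    ``unknown`` to exercise placeholder genus naming downstream.
    """
    from .tables import RANKS, UNKNOWN, TaxonomyTable

    rng = np.random.default_rng(seed)
    tips = tree.tip_names
    n = len(tips)
    targets = {"phylum": max(2, n // 90), "class": max(3, n // 45),
               "order": max(4, n // 24), "family": max(6, n // 12),
               "genus": max(10, n // 6)}
    df = pd.DataFrame(index=tips, columns=list(RANKS), dtype=object)
    for rank in RANKS:
        # cut the tree: walk preorder, splitting the largest group until
        # the target number of monophyletic groups is reached
        groups = [frozenset(tips)]
        frontier = {frozenset(tips): tree.root}
        while len(groups) < targets[rank]:
            groups.sort(key=len, reverse=True)
            big = groups[0]
            node = frontier[big]
            kids = [c for c in node.children]
            if not kids or all(c.is_tip() for c in kids) and len(big) <= 1:
                break
            groups = groups[1:]
            for c in kids:
                mem = frozenset(t.name for t in c.tips(include_self=True))
                groups.append(mem)
                frontier[mem] = c
        label_of = {}
        for gi, g in enumerate(sorted(groups, key=lambda s: min(s))):
            name = f"{rank.capitalize()}{gi + 1}"
            for t in g:
                label_of[t] = name
        df[rank] = [label_of[t] for t in tips]
    mask = rng.random(n) < unknown_genus_frac
    df.loc[mask, "genus"] = UNKNOWN
    return TaxonomyTable(df)


@dataclass
class SimulatedDataset:
    tree: PhyloTree
    meta: SampleMetadata
    table: AsvTable
    truth: pd.DataFrame
    design: SimulationDesign


def simulate_dataset(design: SimulationDesign,
                     plant_defaults: bool = False) -> SimulatedDataset:
    """Tree + metadata + counts (+ default planted effects) in one call."""
    tree = simulate_tree(design.n_tips, _streams(design.seed)["tree"])
    if plant_defaults and not design.effects:
        design = replace(design, effects=choose_default_effects(tree, design))
    meta = simulate_metadata(design)
    table, truth = simulate_counts(design, tree, meta)
    return SimulatedDataset(tree, meta, table, truth, design)


# -- recovery scoring against the truth table -------------------------

def score_recovery(result, truth: pd.DataFrame, members: dict) -> dict:
    """Sensitivity and empirical FDR of one battery against the truth.

    Sensitivity counts exactly the planted clades recovered in their
    scoped family.  For the FDR, a discovery is counted false only if
    its member tips carry no planted signal at all (for any covariate):
    ancestors and descendants of a planted clade share its signal, and
    the design's covariate correlations (IL-6 rises with age and with
    zinc deficiency) make clades planted for one covariate genuinely
    associated with the others, so tip overlap with the union of
    planted tips is the correct non-null criterion.
    """
    battery = result.battery
    sub = truth[truth["covariate"] == battery]
    planted = 0
    recovered = 0
    sig = result.significant
    for _, row in sub.iterrows():
        if battery == "diet":
            fam = f"{row['age']}_{row['study']}"
        elif battery == "il6":
            fam = row["age"]
        else:
            fam = "all"
        planted += 1
        hit = sig[(sig["clade_id"] == row["clade_id"])
                  & ((sig["family"] == fam) if fam != "all" else True)]
        recovered += int(len(hit) > 0)
    all_planted: set = set()
    for tips in truth["member_tips"]:
        all_planted |= set(tips.split(","))
    false = 0
    total = 0
    for _, row in sig.iterrows():
        total += 1
        if not (members[row["clade_id"]] & all_planted):
            false += 1
    return {
        "battery": battery,
        "planted": planted,
        "recovered": recovered,
        "sensitivity": recovered / planted if planted else np.nan,
        "discoveries": total,
        "false_discoveries": false,
        "fdp": false / total if total else 0.0,
    }
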
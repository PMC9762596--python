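"""Run configuration and end-to-end orchestration.

``run_pipeline`` drives filter -> rarefy -> clade matrix -> regression
batteries -> genus screens and writes a reproducible output bundle:
result TSVs, an annotated newick, a manifest recording every seed and
threshold (a run is reconstructible from manifest + inputs), and a
plain-text log.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .batteries import (combined_significant, run_age_battery,
                        run_diet_battery, run_il6_battery)
from .clades import build_clade_matrix
from .screens import kruskal_screen, wilcoxon_screen
from .simulate import (SimulationDesign, simulate_dataset, simulate_taxonomy)
from .tables import (AsvTable, SampleMetadata, TaxonomyTable, agglomerate,
                     assign_placeholder_genus, prevalence_filter, rarefy,
                     relative_abundance)
from .tree import (PhyloTree, ValidationError, midpoint_root, prune_tips,
                   read_newick, write_newick)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Pipeline configuration: file inputs or a simulation design.

    Exactly one of (tree/counts/metadata paths) or ``design`` must be
    provided.  CLI flags override file values which override defaults.
    """
    out_dir: str = "cladal_out"
    tree: str | None = None
    counts: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    design: SimulationDesign | None = None
    plant_defaults: bool = False
    features_in_rows: bool = False
    midpoint: bool = False            # midpoint-root the input tree first
    prevalence_min_samples: int = 5
    rarefaction_depth: int | None = None   # default: minimum retained total
    rarefaction_seed: int = 0
    alpha: float = 0.05
    n_quad: int = 7
    run_age: bool = True
    run_diet: bool = True
    run_il6: bool = True
    run_screens: bool = True

    def __post_init__(self):
        has_files = self.tree is not None and self.counts is not None \
            and self.metadata is not None
        if has_files == (self.design is not None):
            raise ValidationError(
                "provide either input paths (tree, counts, metadata) or a "
                "simulation design, not both or neither"
            )
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.rarefaction_depth is not None and self.rarefaction_depth <= 0:
            raise ValidationError("rarefaction_depth must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        design = raw.pop("design", None)
        if design is not None and not isinstance(design, SimulationDesign):
            design = SimulationDesign(**design)
        return cls(design=design, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunBundle:
    """In-memory handle on a completed run."""
    out_dir: Path
    manifest: dict
    ctu: object
    batteries: dict = field(default_factory=dict)
    screens: dict = field(default_factory=dict)


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> RunBundle:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    manifest: dict = {
        "cladal_version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "errors": {},
    }

    # ---- inputs ------------------------------------------------------
    if config.design is not None:
        ds = simulate_dataset(config.design, plant_defaults=config.plant_defaults)
        tree, table, meta = ds.tree, ds.table, ds.meta
        tax = simulate_taxonomy(tree, seed=config.design.seed)
        write_newick(tree, out / "simulated_tree.nwk")
        table.to_tsv(out / "simulated_counts.tsv")
        tax.to_tsv(out / "simulated_taxonomy.tsv")
        meta.to_tsv(out / "simulated_metadata.tsv")
        _write_df(ds.truth.set_index("clade_id"), out / "simulated_truth.tsv")
        log(f"simulated dataset: {table.shape[0]} samples x {table.shape[1]} ASVs, "
            f"{len(ds.truth)} planted effects (seed {config.design.seed})")
    else:
        tree = read_newick(config.tree)
        table = AsvTable.read_tsv(config.counts,
                                  features_in_rows=config.features_in_rows)
        meta = SampleMetadata.read_tsv(config.metadata)
        tax = TaxonomyTable.read_tsv(config.taxonomy) if config.taxonomy else None
        log(f"inputs: {table.shape[0]} samples x {table.shape[1]} ASVs, "
            f"{tree.n_tips} tree tips")

    meta.check_covers(table.sample_ids)
    if config.midpoint:
        tree = midpoint_root(tree)
        log("midpoint-rooted the input tree")
    shared = set(tree.tip_names) & set(table.feature_ids)
    if not shared:
        raise ValidationError("tree tips and table features are disjoint")
    if shared != set(tree.tip_names):
        tree = prune_tips(tree, shared)
        log(f"pruned tree to {len(shared)} tips shared with the count table")

    # ---- taxonomy / placeholder genera -------------------------------
    if tax is not None:
        tax = assign_placeholder_genus(tax)

    # ---- filter + rarefy ---------------------------------------------
    filt = prevalence_filter(table, config.prevalence_min_samples)
    log(f"prevalence filter (>= {config.prevalence_min_samples} samples): "
        f"{table.shape[1]} -> {filt.shape[1]} ASVs")
    manifest["stages"]["prevalence_filter"] = {
        "min_samples": config.prevalence_min_samples,
        "features_in": table.shape[1], "features_out": filt.shape[1],
    }
    shared = set(tree.tip_names) & set(filt.feature_ids)
    if shared != set(tree.tip_names):
        tree = prune_tips(tree, shared)

    depth = config.rarefaction_depth
    if depth is None:
        depth = int(filt.sample_totals().min())
    rar = rarefy(filt, depth, seed=config.rarefaction_seed)
    log(f"rarefied to depth {depth} (seed {config.rarefaction_seed}): "
        f"{filt.shape[0]} -> {rar.shape[0]} samples")
    manifest["stages"]["rarefaction"] = {
        "depth": depth, "seed": config.rarefaction_seed,
        "samples_in": filt.shape[0], "samples_out": rar.shape[0],
    }

    # ---- clade matrix -------------------------------------------------
    ctu = build_clade_matrix(tree, rar, tax=tax)
    log(f"clade matrix: {ctu.n_clades} clades from {tree.n_tips} tips")
    manifest["stages"]["clades"] = {"n_tips": tree.n_tips,
                                    "n_clades": ctu.n_clades}
    _write_df(ctu.abundances, out / "clade_matrix.tsv")
    _write_df(ctu.manifest(), out / "clade_manifest.tsv")
    annotated = tree.copy()
    for node in annotated.root.preorder(include_self=True):
        if not node.is_tip():
            from .clades import clade_id_for
            node.name = clade_id_for(frozenset(t.name for t in node.tips()))
    write_newick(annotated, out / "annotated_tree.nwk")

    # ---- batteries -----------------------------------------------------
    bundle = RunBundle(out_dir=out, manifest=manifest, ctu=ctu)
    meta_sub = meta.subset(ctu.sample_ids)
    runners = []
    if config.run_age:
        runners.append(("age", lambda: run_age_battery(ctu, meta_sub,
                                                       alpha=config.alpha)))
    if config.run_diet:
        runners.append(("diet", lambda: run_diet_battery(
            ctu, meta_sub, alpha=config.alpha, n_quad=config.n_quad)))
    if config.run_il6:
        runners.append(("il6", lambda: run_il6_battery(ctu, meta_sub,
                                                       alpha=config.alpha)))
    for name, fn in runners:
        try:
            res = fn()
        except Exception as exc:  # partial failure is recorded, not fatal
            manifest["errors"][f"battery_{name}"] = str(exc)
            log(f"battery {name} FAILED: {exc}")
            continue
        bundle.batteries[name] = res
        tbl = res.table.copy()
        if ctu.taxonomy_labels:
            tbl.insert(1, "consensus_taxonomy",
                       tbl["clade_id"].map(ctu.taxonomy_labels))
        _write_df(tbl.set_index("clade_id"), out / f"battery_{name}.tsv")
        counts = res.counts()
        manifest["stages"][f"battery_{name}"] = {
            "families": counts.to_dict(orient="records"),
            "skipped": res.skipped,
        }
        log(f"battery {name}: {int(res.table['significant'].sum())} significant "
            f"clades of {len(res.table)} fits"
            + (f"; skipped families: {res.skipped}" if res.skipped else ""))

    sig = combined_significant(list(bundle.batteries.values()))
    if ctu.taxonomy_labels and len(sig):
        sig.insert(1, "consensus_taxonomy",
                   sig["clade_id"].map(ctu.taxonomy_labels))
    sig = sig.assign(direction=["+" if s > 0 else "-" for s in sig["slope"]]) \
        if len(sig) else sig
    _write_df(sig.set_index("clade_id") if len(sig) else sig,
              out / "significant_clades.tsv")

    # ---- genus screens -------------------------------------------------
    if config.run_screens and tax is not None:
        genus = agglomerate(rar, tax, "genus")
        rel = relative_abundance(genus)
        md = meta_sub.data.loc[rel.index]
        try:
            wil = wilcoxon_screen(rel, md["age"], alpha=config.alpha)
            bundle.screens["wilcoxon_age"] = wil
            _write_df(wil, out / "screen_wilcoxon_age.tsv")
            log(f"age screen: {int(wil['significant'].sum())} of {len(wil)} "
                "genera significant")
        except Exception as exc:
            manifest["errors"]["screen_wilcoxon"] = str(exc)
        wk6 = md[md["timepoint"] == "wk6"].index
        try:
            kw, skipped = kruskal_screen(rel.loc[wk6], md["diet"], md["age"],
                                         alpha=config.alpha)
            for stratum, df in kw.items():
                bundle.screens[f"kruskal_{stratum}"] = df
                _write_df(df, out / f"screen_kruskal_{stratum}.tsv")
                log(f"diet screen ({stratum}): {int(df['significant'].sum())} "
                    f"of {len(df)} genera significant")
            manifest["stages"]["kruskal_screen"] = {"skipped": skipped}
        except Exception as exc:
            manifest["errors"]["screen_kruskal"] = str(exc)

    # ---- manifest + log -------------------------------------------------
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return bundle


def summarize_run(bundle: RunBundle) -> str:
    """Human-readable per-battery and per-family report."""
    lines = [f"cladal run summary ({bundle.out_dir})", "=" * 40]
    for name, res in bundle.batteries.items():
        lines.append(f"\nbattery: {name}")
        counts = res.counts()
        if len(counts):
            lines.append(counts.to_string(index=False))
        for fam, reason in res.skipped.items():
            lines.append(f"  family {fam}: skipped ({reason})")
        sig = res.significant
        if len(sig):
            top = sig.reindex(sig["slope"].abs()
                              .sort_values(ascending=False).index).head(10)
            lines.append("  top clades by |slope|:")
            for _, row in top.iterrows():
                label = bundle.ctu.taxonomy_labels.get(row["clade_id"], "")
                lines.append(
                    f"    {row['clade_id']} family={row['family']} "
                    f"slope={row['slope']:+.3f} q={row['q']:.3g} {label}"
                )
    for name, df in bundle.screens.items():
        lines.append(f"\nscreen: {name}: {int(df['significant'].sum())} of "
                     f"{len(df)} taxa significant")
    if bundle.manifest.get("errors"):
        lines.append(f"\nerrors: {bundle.manifest['errors']}")
    return "\n".join(lines)
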
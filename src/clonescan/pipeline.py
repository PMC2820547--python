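"""Orchestration of the full clonality-vs-recombination analysis.

``run_full_analysis`` takes a multilocus dataset (or per-locus alignment
files), a clade definition (explicit strain groups or ``"auto"`` via GCPSR),
and one master seed, and produces a machine-readable report: site statistics,
per-clade clone correction, Phi / IA / PHT results, split-decomposition
summaries with the networked flag, the GCPSR species partition, an FST scan
over geographic groups, and (optionally) a Phi boundary-expansion
trajectory.  Stages are isolated: a precondition failure in one analysis is
recorded in the report and never alters another stage's numbers.  Reports
are regenerable bit-identically from inputs + master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib

import numpy as np

from . import __version__
from .distances import k3st_distance
from .gcpsr import CladeSet, bootstrap_support, gcpsr_recognize, phi_boundary_expand
from .recombtests import fst_all_pairs, ia_test, pht_test, phi_test
from .seqdata import (
    MultiLocusDataset,
    classify_sites,
    clone_correct,
    concatenate,
    read_alignment,
    read_metadata,
)
from .splitsnet import fit_percentage, is_networked, split_decomposition

__all__ = ["run_full_analysis", "write_report", "summary_markdown"]

log = logging.getLogger("clonescan")


def _seed_for(master: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode())
    return int(np.random.SeedSequence([master, tag]).generate_state(1)[0] % 2**31)


def _stage(report_errors: dict, name: str, fn):
    try:
        return fn()
    except Exception as exc:  # record, keep siblings running
        log.info("stage %s failed: %s", name, exc)
        report_errors[name] = str(exc)
        return None


def _digest(ds: MultiLocusDataset) -> str:
    h = hashlib.sha256()
    for loc in ds.loci:
        h.update(loc.locus_name.encode())
        for t, r in zip(loc.taxa, loc.rows):
            h.update(t.encode())
            h.update(r.encode())
    return h.hexdigest()


def _site_block(aln) -> dict:
    sc = classify_sites(aln)
    return {
        "length": sc.length,
        "constant": sc.n_constant,
        "variable": sc.n_variable,
        "singleton": sc.n_singleton,
        "parsimony_informative": sc.n_parsimony_informative,
        "all_missing": sc.n_all_missing,
    }


def run_full_analysis(
    dataset: MultiLocusDataset | None = None,
    locus_paths: list[str] | None = None,
    metadata_path: str | None = None,
    clades: dict[str, list[str]] | str = "auto",
    seed: int = 0,
    tests: tuple[str, ...] = ("phi", "ia", "pht"),
    run_splits: bool = True,
    run_gcpsr: bool = True,
    run_fst: bool = True,
    boundary: dict | None = None,
    phi_params: dict | None = None,
    ia_params: dict | None = None,
    pht_params: dict | None = None,
    n_boot: int = 500,
    fst_clade: str | None = None,
) -> dict:
    """Execute the full analysis and return the report dictionary.

    ``clades`` maps clade names to strain lists, or is ``"auto"`` to take
    the GCPSR species partition (blocks of >= 3 strains) as clades.
    ``boundary`` optionally holds ``{"seed_set": [...], "candidates":
    {name: [...]}, "policy": ..., "alpha": ...}``.
    """
    errors: dict[str, str] = {}
    if dataset is None:
        if not locus_paths:
            raise ValueError("either a dataset or locus_paths is required")
        loci = [read_alignment(p, _guess_format(p)) for p in locus_paths]
        meta = read_metadata(metadata_path) if metadata_path else {}
        dataset = concatenate(loci, metadata=meta)
    ds = dataset
    concat = ds.concatenated()
    phi_params = dict(phi_params or {})
    ia_params = dict(ia_params or {})
    pht_params = dict(pht_params or {})

    report: dict = {
        "tool": "clonescan",
        "version": __version__,
        "master_seed": seed,
        "input": {
            "digest_sha256": _digest(ds),
            "n_strains": ds.n_taxa,
            "loci": [loc.locus_name for loc in ds.loci],
            "partition_map": [list(p) for p in ds.partition_map],
        },
        "sites": {},
        "gcpsr": None,
        "clades": {},
        "fst": None,
        "boundary": None,
        "errors": errors,
    }
    log.info("master seed = %d, input digest = %s", seed, report["input"]["digest_sha256"][:12])

    # --- site statistics ------------------------------------------------
    for loc in ds.loci:
        report["sites"][loc.locus_name] = _site_block(loc)
    report["sites"]["concatenated"] = _site_block(concat)

    # --- GCPSR ----------------------------------------------------------
    partition = None
    if run_gcpsr or clades == "auto":
        def do_gcpsr():
            clade_sets = []
            for loc in ds.loci:
                s = _seed_for(seed, f"bootstrap:{loc.locus_name}")
                log.info("bootstrap %s: n_boot=%d seed=%d", loc.locus_name, n_boot, s)
                tree = bootstrap_support(loc, n_boot=n_boot, seed=s)
                clade_sets.append(CladeSet.from_tree(tree, loc.locus_name))
            recognized, part = gcpsr_recognize(clade_sets)
            return {
                "n_recognized": len(recognized),
                "recognized": [sorted(k) for k in recognized],
                "partition": [sorted(b) for b in part],
            }, part

        out = _stage(errors, "gcpsr", do_gcpsr)
        if out is not None:
            report["gcpsr"], partition = out

    clade_map: dict[str, list[str]] = {}
    if clades == "auto":
        if partition is not None:
            for i, block in enumerate(
                sorted([b for b in partition if len(b) >= 3],
                       key=lambda b: (-len(b), sorted(b)))
            ):
                clade_map[f"species{i+1}"] = sorted(block)
        else:
            errors["clades"] = "auto clade definition unavailable (gcpsr failed)"
    else:
        clade_map = {k: list(v) for k, v in clades.items()}

    # --- per-clade analyses ---------------------------------------------
    for name in sorted(clade_map):
        strains = clade_map[name]
        block: dict = {"strains": strains, "n": len(strains)}
        sub = ds.subset(strains)
        sub_concat = sub.concatenated()

        def do_clone():
            cc, mapping = clone_correct(sub)
            return {"n_retained": cc.n_taxa,
                    "removed": {k: v for k, v in mapping.items() if v}}

        block["clone_correction"] = _stage(errors, f"clone_correct:{name}", do_clone)

        if "phi" in tests:
            s = _seed_for(seed, f"phi:{name}")
            block["phi"] = _stage(
                errors, f"phi:{name}",
                lambda: phi_test(sub_concat, seed=s, **phi_params).to_dict(),
            )
            if block["phi"]:
                log.info("phi[%s]: n_perm=%d seed=%d", name, block["phi"]["n_permutations"], s)
        if "ia" in tests:
            s = _seed_for(seed, f"ia:{name}")
            block["ia"] = _stage(
                errors, f"ia:{name}",
                lambda: ia_test(sub, seed=s, **ia_params).to_dict(),
            )
        if "pht" in tests:
            s = _seed_for(seed, f"pht:{name}")
            block["pht"] = _stage(
                errors, f"pht:{name}",
                lambda: pht_test(sub, seed=s, **pht_params).to_dict(),
            )
        if run_splits:
            def do_splits():
                dm = k3st_distance(sub_concat, cap=True)
                ss = split_decomposition(dm)
                return {
                    "n_splits": ss.n_splits,
                    "n_nontrivial": len(ss.nontrivial()),
                    "fit_percent": fit_percentage(ss, dm),
                    "networked": is_networked(ss),
                    "n_capped_pairs": len(dm.capped_pairs),
                }

            block["splits"] = _stage(errors, f"splits:{name}", do_splits)
        report["clades"][name] = block

    # --- FST over geographic groups --------------------------------------
    if run_fst:
        def do_fst():
            if fst_clade is not None:
                target = ds.subset(clade_map[fst_clade]).concatenated()
            else:
                target = concat
            if not ds.metadata:
                raise ValueError("FST requested but no metadata provided")
            table = fst_all_pairs(target, ds.metadata)
            vals = table["fst"].dropna()
            return {
                "pairs": table.to_dict(orient="records"),
                "max_fst": (float(vals.max()) if len(vals) else None),
                "clade": fst_clade,
            }

        report["fst"] = _stage(errors, "fst", do_fst)

    # --- boundary expansion ----------------------------------------------
    if boundary:
        def do_boundary():
            s = _seed_for(seed, "boundary")
            traj = phi_boundary_expand(
                concat,
                boundary["seed_set"],
                boundary["candidates"],
                policy=boundary.get("policy", "groups"),
                alpha=boundary.get("alpha", 0.05),
                n_perm=boundary.get("n_perm", phi_params.get("n_perm", 1000)),
                window_w=boundary.get("window_w", phi_params.get("window_w", 100)),
                seed=s,
            )
            return traj.to_dict()

        report["boundary"] = _stage(errors, "boundary", do_boundary)

    return report


def _guess_format(path: str) -> str:
    p = str(path).lower()
    return "nexus" if p.endswith((".nex", ".nexus", ".nxs")) else "fasta"


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")


def summary_markdown(report: dict) -> str:
    lines = [
        f"# clonescan report (seed {report['master_seed']})",
        "",
        "## Sites",
        "| partition | length | constant | informative |",
        "|---|---|---|---|",
    ]
    for name, s in report["sites"].items():
        lines.append(
            f"| {name} | {s['length']} | {s['constant']} | {s['parsimony_informative']} |"
        )
    lines += ["", "## Clades",
              "| clade | n | Phi p | IA | IA p | PHT p | networked |",
              "|---|---|---|---|---|---|---|"]
    for name, b in report.get("clades", {}).items():
        def g(key, sub):
            d = b.get(key)
            return d.get(sub) if isinstance(d, dict) else None

        def fmt(v):
            return f"{v:.4g}" if isinstance(v, (int, float)) else "-"

        lines.append(
            "| {} | {} | {} | {} | {} | {} | {} |".format(
                name, b["n"], fmt(g("phi", "p_value")), fmt(g("ia", "statistic")),
                fmt(g("ia", "p_value")), fmt(g("pht", "p_value")),
                (b.get("splits") or {}).get("networked", "-"),
            )
        )
    if report.get("gcpsr"):
        lines += ["", "## GCPSR partition"]
        for block in report["gcpsr"]["partition"]:
            lines.append(f"- {{{', '.join(block)}}}")
    if report.get("fst"):
        lines += ["", f"Max pairwise FST over geographic groups: {report['fst']['max_fst']}"]
    if report.get("errors"):
        lines += ["", "## Stage errors"]
        for k, v in sorted(report["errors"].items()):
            lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"
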
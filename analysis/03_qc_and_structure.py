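#!/usr/bin/env python
"""Panel QC and population structure on the simulated study: call-rate/MAF
filtering, LD pruning, relative flagging, IBS-MDS, breed-size balancing,
Reynolds distances and a bootstrapped NJ tree.

Writes the QC report, MDS coordinates, distance matrix and Newick tree
under results/.
"""

from pathlib import Path

import pandas as pd

from flockscape.differentiation import bootstrap_nj_tree, reynolds_matrix
from flockscape.qc import (QcParams, balance_breeds, filter_panel,
                           flag_relatives, ibs_mds, ld_prune)
from flockscape.sim import simulate_panel

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location(
    "sim_cfg", Path(__file__).with_name("01_simulate_panels.py"))
_mod = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
CONFIG = _mod.CONFIG

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel, _ = simulate_panel(CONFIG)
    params = QcParams(seed=CONFIG.seed)
    filtered, report = filter_panel(panel, params)
    print(f"QC: {panel.n_samples}x{panel.n_snps} -> "
          f"{filtered.n_samples}x{filtered.n_snps} "
          f"({len(report)} removals)")
    report.to_csv(RESULTS / "qc_report.tsv", sep="\t", index=False,
                  lineterminator="\n")

    flags = flag_relatives(filtered, params)
    print(f"relative screen: {len(flags)} flagged pairs "
          f"({(flags['flag'] == 'duplicate').sum()} duplicates)")

    kept_snps = ld_prune(filtered.take_snps(range(0, filtered.n_snps, 4)),
                         params)
    print(f"LD pruning on a 1-in-4 thinned panel retained {len(kept_snps)} "
          "SNPs")

    coords = ibs_mds(filtered, n_dims=10)
    coords.to_csv(RESULTS / "mds_coordinates.tsv", sep="\t", index=False,
                  lineterminator="\n")
    kept = balance_breeds(filtered, coords, params)
    print(f"breed balancing kept {len(kept)} of {filtered.n_samples} samples")

    labels, D = reynolds_matrix(filtered)
    pd.DataFrame(D, index=labels, columns=labels).to_csv(
        RESULTS / "reynolds_distances.tsv", sep="\t", lineterminator="\n")
    _, newick = bootstrap_nj_tree(filtered, n_boot=100, seed=CONFIG.seed)
    (RESULTS / "reynolds_nj.nwk").write_text(newick + "\n")
    print("NJ tree:", newick[:100], "...")


if __name__ == "__main__":
    main()
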
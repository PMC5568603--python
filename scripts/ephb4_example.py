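#!/usr/bin/env python
"""Optional end-to-end run on the EphB4-EphrinB2 complex (PDB 2HLE).

Not part of the test suite: it needs a locally downloaded structure
(e.g. https://files.rcsb.org/download/2HLE.pdb).  Chain A is the EphB4
receptor; chain B is EphrinB2, whose residues 116-128 form the 13-mer
binding motif.  The motif sequence is docked to the receptor, the
EphrinB2 chain is superposed onto the chosen pose, and — since the input
file is itself the bound complex — every model is scored against it.

With the shipped hydropathy contact table this is a demonstration of
mechanics, not a prediction benchmark: a statistical potential should be
substituted (``--contact-table``) for meaningful pose ranking.

Usage:
    python scripts/ephb4_example.py --pdb 2HLE.pdb --out runs/2hle --seed 1
"""

import argparse
import os
import sys

from slimdock.pipeline import PipelineConfig, run_pipeline
from slimdock.structure_io import read_pdb, write_pdb


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pdb", required=True,
                        help="path to a local copy of PDB entry 2HLE")
    parser.add_argument("--out", required=True)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--receptor-chain", default="A")
    parser.add_argument("--partner-chain", default="B")
    parser.add_argument("--slim", default=None,
                        help="default: <partner chain>:116-128")
    parser.add_argument("--contact-table", default=None,
                        help="CSV contact-energy table replacing the default")
    args = parser.parse_args(argv)

    os.makedirs(args.out, exist_ok=True)
    chains = {c.chain_id: c for c in read_pdb(args.pdb)}
    receptor = chains[args.receptor_chain]
    partner = chains[args.partner_chain]
    receptor_path = os.path.join(args.out, "receptor.pdb")
    partner_path = os.path.join(args.out, "partner.pdb")
    reference_path = os.path.join(args.out, "reference.pdb")
    write_pdb([receptor], receptor_path)
    write_pdb([partner], partner_path)
    write_pdb([receptor, partner], reference_path)

    config = PipelineConfig(
        receptor_path=receptor_path,
        partner_path=partner_path,
        reference_path=reference_path,
        slim=args.slim or f"{args.partner_chain}:116-128",
        out_dir=os.path.join(args.out, "run"),
        seed=args.seed,
        docking={"exchange_interval": 2,
                 **({"contact_table_path": args.contact_table}
                    if args.contact_table else {})},
    )
    manifest = run_pipeline(config)
    print(manifest)
    return 0


if __name__ == "__main__":
    sys.exit(main())
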
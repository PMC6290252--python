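"""Two-stage multi-locus association scan over the SNPLDB markers.

Runs the restricted two-stage scan (stage-1 single-locus F-tests with
eigenvector covariates, stage-2 forward-backward stepwise with
experiment-wise alpha) at the normal (0.02) and stringent (0.0002) levels,
and writes the detected-QTL tables plus per-allele effects.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from soyqtl import genio, pipeline  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--alpha", type=float, default=0.02)
    ap.add_argument("--alpha-stringent", type=float, default=0.0002)
    ap.add_argument("--stage1-p", type=float, default=0.05)
    args = ap.parse_args()
    out = Path(args.out_dir)

    gm = genio.read_vcf(out / "data" / "panel.vcf")
    obs = genio.read_phenotypes(out / "data" / "phenotypes.tsv")
    markers = pipeline.load_markers(out / "markers")
    ev = pd.read_csv(out / "markers" / "eigenvectors.tsv", sep="\t",
                     index_col=0).loc[gm.accession_ids].to_numpy()
    model, stringent, effects = pipeline.gwas_step(
        markers, obs, ev, gm.accession_ids, out / "gwas",
        alpha=args.alpha, alpha_stringent=args.alpha_stringent,
        stage1_p=args.stage1_p)
    total = sum(model.seq_r2.values())
    n_alleles = sum(len(e) for e in effects.effects.values())
    print(f"normal alpha {args.alpha}: {len(model.selected)} QTLs with "
          f"{n_alleles} alleles; total R2 = {100 * total:.2f}%")
    print(f"stringent alpha {args.alpha_stringent}: "
          f"{len(stringent.selected)} QTLs "
          f"(subset of normal: {set(stringent.selected) <= set(model.selected)})")


if __name__ == "__main__":
    main()
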
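"""Variance components, heritability and GCV of the simulated trait.

Fits the RCBD multi-environment ANOVA and reports sigma_g2, sigma_ge2,
sigma_e2, the multi-environment heritability and the genetic coefficient of
variation, plus per-environment single-trial h2.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from soyqtl import genio, pipeline  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    out = Path(args.out_dir)

    obs = genio.read_phenotypes(out / "data" / "phenotypes.tsv")
    df = pipeline.heritability_step(obs, out / "heritability")
    row = df.iloc[0]
    print(f"variance components: sigma_g2={row['sigma_g2']:.2f}, "
          f"sigma_ge2={row['sigma_ge2']:.2f}, sigma_e2={row['sigma_e2']:.2f}")
    print(f"multi-environment h2 = {row['h2_multi_env']:.4f} "
          f"(s={int(row['s'])}, r={int(row['r'])})")
    print(f"GCV = {row['gcv_percent']:.2f}% at mean {row['mean']:.2f}")


if __name__ == "__main__":
    main()
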
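"""Generate the synthetic exposure/mediator/outcome cohorts used downstream.

Writes three aligned summary-statistic files, the block LD matrix and the
truth sidecar to results/data/. The design is the default recovery
configuration: 200 SNPs, cohorts of 100,000, b1 = 0.3, b2 = -0.2,
b_direct = -0.5, no pleiotropy, so the true total effect is -0.56 and the
true proportion mediated 10.71%.
"""

import argparse
from pathlib import Path

from medmr.simulate import SimulationConfig, simulate_ld, simulate_sumstats, truth_frame
from medmr.sumstats import write_sumstats


def main(seed: int = 1, out: Path = Path("results/data")) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=seed, ld_block_size=5, ld_within_block_r2=0.3)
    exposure, mediator, outcome, truth = simulate_sumstats(cfg)
    write_sumstats(exposure, out / "exposure.tsv")
    write_sumstats(mediator, out / "mediator.tsv")
    write_sumstats(outcome, out / "outcome.tsv")
    simulate_ld(cfg).to_csv(out / "ld.tsv", sep="\t")
    truth_frame(truth, [r.snp_id for r in exposure]).to_csv(
        out / "truth.tsv", sep="\t", index=False)
    print(f"wrote {cfg.n_snps}-SNP cohorts (seed {seed}) to {out}")
    print(f"true total effect {truth.beta3:.3f}, "
          f"true proportion mediated {truth.proportion_mediated:.4f}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    main(args.seed, args.out)
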
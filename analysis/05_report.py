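"""One-command reproduction: full pipeline bundle plus summary report.

Runs the whole analysis end to end through the orchestrator (the same
code paths exercised piecewise by 01-04) into results/05_bundle/ and
prints the run report. Re-running with the same seed reproduces the
bundle byte for byte.
"""

from tftri.config import RunConfig, SimConfig
from tftri import pipeline

SEED = 1


def main() -> None:
    cfg = RunConfig(outdir="results/05_bundle", seed=SEED, simulate=SimConfig(seed=SEED))
    pipeline.run_pipeline(cfg)
    print(pipeline.report("results/05_bundle"))


if __name__ == "__main__":
    main()
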
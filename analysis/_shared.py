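"""Shared paths and lazily-regenerated inputs for the analysis drivers."""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SIM_DIR = RESULTS / "sim"

SIM_SEED = 7
SIM_N_GENES = 400


def ensure_sim():
    """Generate the study dataset (annotation, expression, truth) if absent."""
    from splicescape import (
        SimulationConfig,
        intron_table,
        simulate,
        truth_to_frame,
        write_expression_table,
        write_gtf,
    )

    gtf = SIM_DIR / "annotation.gtf"
    if gtf.exists():
        return
    SIM_DIR.mkdir(parents=True, exist_ok=True)
    sim = simulate(SimulationConfig(n_genes=SIM_N_GENES, seed=SIM_SEED))
    write_gtf(sim.genes, gtf)
    write_expression_table(sim.records, SIM_DIR / "expression.tsv")
    truth_to_frame(sim.truth).to_csv(SIM_DIR / "truth.tsv", sep="\t", index=False)
    intron_table(sim.genes).to_csv(SIM_DIR / "introns.tsv", sep="\t", index=False)


def load_sim():
    """The simulated bundle, regenerated deterministically (not re-read)."""
    from splicescape import SimulationConfig, simulate

    ensure_sim()
    return simulate(SimulationConfig(n_genes=SIM_N_GENES, seed=SIM_SEED))
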
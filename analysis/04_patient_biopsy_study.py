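"""Differential infiltration in a 7-vs-8 synovial-biopsy cohort.

Emulates the layout of a clinical spondylarthropathy series: bulk synovial
biopsies from 7 control donors and 8 patients, with dendritic-cell and
CD4+ T fractions each raised by +0.15 in disease.  Scores the cohort with
the panels from 01_build_markers, tests each cell type, and reports which
metagenes separate patients from controls.
"""

from pathlib import Path

from leukomet import SimulationConfig, build_reference_panel, run_cohort_study, write_scores

SEED = 11
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    fitted = build_reference_panel(SimulationConfig(), seed=SEED, k=25)

    cohort_cfg = SimulationConfig(fraction_shift={"DC": 0.15, "CD4T": 0.15})
    study = run_cohort_study(
        cohort_cfg, fitted.panel, fitted.reference.signatures, seed=SEED + 200
    )
    study.scores.dataset_id = "synthetic-synovial-biopsies"
    write_scores(study.scores, RESULTS / "biopsy_scores.tsv")
    study.comparison.write(RESULTS / "biopsy_comparison.tsv")
    study.cohort.fractions.to_csv(RESULTS / "biopsy_true_fractions.tsv", sep="\t",
                                  index_label="sample_id", float_format="%.5f")

    print("7 control vs 8 disease biopsies; shifted: DC, CD4T (+0.15)")
    print(study.comparison.data.to_string(index=False, float_format="%.4f".__mod__))
    hits = study.comparison.significant_types()
    print(f"significant at p<=0.05: {', '.join(hits) if hits else 'none'}")
    print(f"wrote {RESULTS / 'biopsy_comparison.tsv'}")


if __name__ == "__main__":
    main()
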
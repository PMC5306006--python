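"""Run the full pipeline and print the report.

Simulates colonies at the default field scale, computes metrics, extracts
events, runs the nest/trail QAP survival suite and the budding AoD suite,
and writes CSV/JSON/GraphML results plus a plain-text report.  Equivalent
shell command:  polynest run --seed 1 --qap-b 499 --out results_demo"""

from polynest import PipelineConfig, run_pipeline
from polynest.pipeline import format_report
from polynest.simulate import SimConfig

config = PipelineConfig(
    seed=1,
    qap_B=499,  # the full analysis default is 10,000; smaller here for speed
    sim=SimConfig(n_colonies=6),
    out_dir="results_demo",
)
bundle = run_pipeline(config)
print(format_report(bundle))
# Each line is one test: z (Cox/QAP) or chisq (GLMM AoD), sample size, and
# the permutation or chi-squared p-value.  Betweenness effects are planted;
# canopy, tree distance and the colony-level ratio are not.
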
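"""Plan a large serial-sectioning run: yield, time, and cost of the two regimes.

A cubic-millimetre reconstruction at 40 nm section thickness needs ~25,000
consecutive sections with no adjacent pair lost. We compare traditional
one-section-per-grid handling against batch processing (4 substrates per
batch, 40 sections each) at 1% per-section / per-substrate loss rates.
"""

from sstembatch import (
    BatchLayout,
    CostModel,
    ExperimentPlan,
    LossRates,
    TimingModel,
    batched_experiment_yield,
    compare_designs,
    recommend_layout,
    traditional_experiment_yield,
)

plan = ExperimentPlan(n=25000)
rates = LossRates(p=0.01, p_sub=0.01)
layout = BatchLayout(m=4, c=40)

y_trad = traditional_experiment_yield(plan, rates)
y_batch = batched_experiment_yield(plan, layout, rates)
print(f"traditional yield : {y_trad:.3f}  ({y_trad:.0%})")
print(f"batched yield     : {y_batch:.3f}  ({y_batch:.0%})")
print(f"improvement       : {y_batch / y_trad:.1f}x")
# The batched process turns a ~8%-success experiment into a ~91% one by
# keeping consecutive sections on different substrates.

report = compare_designs(TimingModel(), CostModel(), plan, layout)
print(f"\ncollection time   : {report['total_time_traditional'] / 86400:.1f} d traditional, "
      f"{report['total_time_batched'] / 86400:.1f} d batched "
      f"({report['time_ratio']:.1f}x faster)")
print(f"substrate cost    : ${report['total_cost_traditional']:.0f} traditional, "
      f"${report['total_cost_batched']:.0f} batched")
# Cost per section in the batched regime is w/s (wafer cost over sections
# per wafer), independent of n; it falls as wafers grow.

m, c, y = recommend_layout(plan, rates, m_max=20, c_max=80)
print(f"\nbest layout within m<=20, c<=80 : m={m}, c={c} (yield {y:.3f})")
# Few large substrates beat many small ones: failure requires two substrate
# losses in one batch, and fewer batches means fewer chances to fail.
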
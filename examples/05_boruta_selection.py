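"""All-relevant feature selection with Boruta shadow features.

Builds a regression table where exactly 5 of 40 covariates drive the
response (overall R^2 = 0.9), runs Boruta, and shows that the informative
set is confirmed while the noise is rejected.
"""

from eosdm.boruta import boruta_select
from eosdm.synthetic import generate_feature_response

X, y, informative = generate_feature_response(n=60, p=40, k_informative=5, r2=0.9, seed=1)
print(f"{X.shape[1]} covariates, {len(y)} units; truly informative: {informative}")

res = boruta_select(X, y, seed=1, n_trees=250, importance="permutation_mean")
print(f"\nBoruta finished after {res.iterations} iterations")
print(f"confirmed : {sorted(res.confirmed)}")
print(f"tentative : {sorted(res.tentative)} (rough-fix keeps: "
      f"{[n for n in res.tentative if res.rough_fix_keep.get(n)]})")
print(f"rejected  : {len(res.rejected)} covariates")

hit = {n: res.hits[n] for n in informative}
print(f"\nhit counts of the informative covariates: {hit}")
print(f"selected for the SDM: {sorted(res.selected())}")
# confirmed covariates beat the best random shadow in significantly more
# than half of the iterations; rejected ones significantly less.
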
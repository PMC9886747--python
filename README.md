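# cthaem — CT hepatic arteriography enhancement mapping

`cthaem` quantifies residual hepatocellular-carcinoma (HCC) enhancement
immediately after drug-eluting-beads transarterial chemoembolization
(DEB-TACE) from dual-phase CT hepatic arteriography (CTHA): a native
(non-contrast) and an intra-arterial contrast-enhanced acquisition obtained
before and after embolization. The clinical problem: after DEB-TACE the
tumor retains contrast ("stasis"), so on a plain post-treatment arteriogram
residual viable tumor and harmless contrast pooling look alike. Subtracting
the registered native phase from the arterial phase cancels the stasis —
which is bright in *both* phases — and leaves only true arterial
enhancement.

The package is aimed at interventional-radiology researchers who want a
reproducible, fully parameterised implementation of the workflow, plus a
synthetic phantom generator with complete ground truth for validation.

## Method

For each session (pre- and post-treatment):

1. **Deformable registration** of the native onto the arterial phase
   (multiresolution symmetric-forces demons with histogram matching and HU
   clipping — same-modality CT, small respiratory deformation).
2. **Enhancement map (EM)**: `EM = arterial − warp(native)`, signed ΔHU, no
   smoothing, computed at full resolution. Stasis subtracts to ~0 ("void");
   viable tumor keeps its arterial uplift.

Then, across sessions:

3. **Rigid co-registration** of the post-treatment map onto the
   pre-treatment grid (anchored on the arterial volumes).
4. **Relative enhancement**: with `ROI_tumor` the largest tumor
   cross-section (axial or coronal) and `ROI_normal` a 300 mm² disc of
   vessel-free contralateral parenchyma,

   ```
   T_RE = mean(EM | ROI_tumor) / mean(EM | ROI_normal)
   ```

   computed pre (`T_pre_RE`) and post (`T_post_RE`). Post-treatment, the
   tumor mean is restricted to voxels with EM > τ (default τ = 0 ΔHU) so
   stasis voids do not bias the normalisation. The response call is
   **residual** iff `T_post_RE > 1`.
5. **Feeder tracing** (residual calls only): residual-enhancement regions
   are supra-threshold components of the tumor; a Hessian vesselness filter
   plus minimal-cost path search traces the artery from the hepatic root to
   each region, and traces are classified *persistent feeder* vs *new
   collateral* by overlap with the pre-treatment vessel mask. Thin-slab
   (5–10 mm) MIPs are rendered for QC.
6. **Evaluation**: cross-tabulation of calls against reference response
   labels (mRECIST CR vs PR/SD) with exact Clopper–Pearson 95% CIs, and
   Wilcoxon rank-sum comparison of `T_post_RE` between groups (exact by
   enumeration for n ≤ 20).

## Worked example

```python
from cthaem.phantom import PhantomSpec, generate_case
from cthaem.pipeline import CaseData, RunConfig, run_case_data

spec = PhantomSpec(residual_fraction=0.5, noise_sigma_hu=8.0,
                   deformation_amplitude_mm=3.0, seed=5)
case = generate_case(spec)
report = run_case_data(CaseData.from_phantom(case), RunConfig())
r = report["response"]
print(r["T_pre_RE"], r["T_post_RE"], r["call"])
print(report["feeders"][0]["trace"]["status"])
```

prints

```
2.865406 2.083687 residual
persistent_feeder
```

The phantom's tumor enhances 60 ΔHU against a 20 ΔHU parenchymal uplift, so
the pre-treatment relative enhancement is ≈ 3. After "treatment" half the
tumor volume still enhances: the high-attenuation-subset statistic stays
well above 1 (2.08 here; image noise admits some near-zero stasis voxels
into the subset, diluting the analytic 3.0), the case is correctly called
residual, and the traced artery is recognised as the original feeder. On
noise-free phantoms the statistic recovers the analytic values exactly
(whole-ROI 1.5 vs subset 3.0 at 50% residual).

The same workflow is available from the shell:

```
cthaem simulate cohort/ --n-cases 10 --prevalence 0.4 --seed 0
cthaem run-cohort cohort/manifest.json --output-dir results/
cthaem evaluate calls.csv labels.csv
```

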
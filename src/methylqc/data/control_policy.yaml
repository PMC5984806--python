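# Default control-metric policy: 17 BeadArray control metrics.
#
# Each metric is the ratio (mean intensity of the numerator probe group in
# its channel) / (mean of the denominator group in its channel); a sample is
# flagged when the value falls strictly below the threshold. Probe groups
# are selected by regular expressions over control probe identifiers, so the
# table can be edited to match any manifest's naming scheme. The groupings
# and thresholds follow the manufacturer's controls-reporter conventions as
# an editable approximation: 5.0 for staining/extension/non-polymorphic,
# 0.0 for restoration, 1.0 otherwise.
metrics:
  - name: Restoration
    numerator: {pattern: "^ctl_restoration", channel: grn}
    denominator: {pattern: "^ctl_negative", channel: grn}
    threshold: 0.0
  - name: Staining green
    numerator: {pattern: "^ctl_staining_biotin_high", channel: grn}
    denominator: {pattern: "^ctl_staining_biotin_bkg", channel: grn}
    threshold: 5.0
  - name: Staining red
    numerator: {pattern: "^ctl_staining_dnp_high", channel: red}
    denominator: {pattern: "^ctl_staining_dnp_bkg", channel: red}
    threshold: 5.0
  - name: Extension green
    numerator: {pattern: "^ctl_extension_[cg]$", channel: grn}
    denominator: {pattern: "^ctl_extension_[at]$", channel: grn}
    threshold: 5.0
  - name: Extension red
    numerator: {pattern: "^ctl_extension_[at]$", channel: red}
    denominator: {pattern: "^ctl_extension_[cg]$", channel: red}
    threshold: 5.0
  - name: Hybridization high/medium
    numerator: {pattern: "^ctl_hyb_high", channel: grn}
    denominator: {pattern: "^ctl_hyb_medium", channel: grn}
    threshold: 1.0
  - name: Hybridization medium/low
    numerator: {pattern: "^ctl_hyb_medium", channel: grn}
    denominator: {pattern: "^ctl_hyb_low", channel: grn}
    threshold: 1.0
  - name: Target removal 1
    numerator: {pattern: "^ctl_extension_[at]$", channel: grn}
    denominator: {pattern: "^ctl_target_removal_1", channel: grn}
    threshold: 1.0
  - name: Target removal 2
    numerator: {pattern: "^ctl_extension_[at]$", channel: grn}
    denominator: {pattern: "^ctl_target_removal_2", channel: grn}
    threshold: 1.0
  - name: Bisulfite conversion I green
    numerator: {pattern: "^ctl_bc1_c[123]$", channel: grn}
    denominator: {pattern: "^ctl_bc1_u[123]$", channel: grn}
    threshold: 1.0
  - name: Bisulfite conversion I red
    numerator: {pattern: "^ctl_bc1_c[456]$", channel: red}
    denominator: {pattern: "^ctl_bc1_u[456]$", channel: red}
    threshold: 1.0
  - name: Bisulfite conversion II
    numerator: {pattern: "^ctl_bc2_", channel: red}
    denominator: {pattern: "^ctl_bc2_", channel: grn}
    threshold: 1.0
  - name: Specificity I green
    numerator: {pattern: "^ctl_spec1_pm_g", channel: grn}
    denominator: {pattern: "^ctl_spec1_mm_g", channel: grn}
    threshold: 1.0
  - name: Specificity I red
    numerator: {pattern: "^ctl_spec1_pm_r", channel: red}
    denominator: {pattern: "^ctl_spec1_mm_r", channel: red}
    threshold: 1.0
  - name: Specificity II
    numerator: {pattern: "^ctl_spec2_", channel: red}
    denominator: {pattern: "^ctl_spec2_", channel: grn}
    threshold: 1.0
  - name: Non-polymorphic green
    numerator: {pattern: "^ctl_np_[cg]$", channel: grn}
    denominator: {pattern: "^ctl_np_[at]$", channel: grn}
    threshold: 5.0
  - name: Non-polymorphic red
    numerator: {pattern: "^ctl_np_[at]$", channel: red}
    denominator: {pattern: "^ctl_np_[cg]$", channel: red}
    threshold: 5.0
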
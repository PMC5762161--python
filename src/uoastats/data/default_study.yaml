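# Default Monte-Carlo study grid: null-effect operating characteristics of the
# naive, subject-based and mixed analyses for two-level clustered designs.
# Subject-level ICC in {0, 0.1, 0.5} crossed with cluster size m in {2, 5, 20},
# 20 subjects per group, total variance 1 (sigma_subject = sqrt(ICC),
# sigma_resid = sqrt(1 - ICC)). All results are labelled with this file.
n_reps: 1000
alpha: 0.05
scenarios:
- name: icc0.0_m2
  layout: {n_groups: 2, subjects_per_group: 20, samples_per_subject: 2, replicates_per_sample: 1}
  components: {sigma_subject: 0.0, sigma_sample: null, sigma_resid: 1.0}
  effect: 0.0
- name: icc0.0_m5
  layout: {n_groups: 2, subjects_per_group: 20, samples_per_subject: 5, replicates_per_sample: 1}
  components: {sigma_subject: 0.0, sigma_sample: null, sigma_resid: 1.0}
  effect: 0.0
- name: icc0.0_m20
  layout: {n_groups: 2, subjects_per_group: 20, samples_per_subject: 20, replicates_per_sample: 1}
  components: {sigma_subject: 0.0, sigma_sample: null, sigma_resid: 1.0}
  effect: 0.0
- name: icc0.1_m2
  layout: {n_groups: 2, subjects_per_group: 20, samples_per_subject: 2, replicates_per_sample: 1}
  components: {sigma_subject: 0.31622776601683794, sigma_sample: null, sigma_resid: 0.9486832980505138}
  effect: 0.0
- name: icc0.1_m5
  layout: {n_groups: 2, subjects_per_group: 20, samples_per_subject: 5, replicates_per_sample: 1}
  components: {sigma_subject: 0.31622776601683794, sigma_sample: null, sigma_resid: 0.9486832980505138}
  effect: 0.0
- name: icc0.1_m20
  layout: {n_groups: 2, subjects_per_group: 20, samples_per_subject: 20, replicates_per_sample: 1}
  components: {sigma_subject: 0.31622776601683794, sigma_sample: null, sigma_resid: 0.9486832980505138}
  effect: 0.0
- name: icc0.5_m2
  layout: {n_groups: 2, subjects_per_group: 20, samples_per_subject: 2, replicates_per_sample: 1}
  components: {sigma_subject: 0.7071067811865476, sigma_sample: null, sigma_resid: 0.7071067811865476}
  effect: 0.0
- name: icc0.5_m5
  layout: {n_groups: 2, subjects_per_group: 20, samples_per_subject: 5, replicates_per_sample: 1}
  components: {sigma_subject: 0.7071067811865476, sigma_sample: null, sigma_resid: 0.7071067811865476}
  effect: 0.0
- name: icc0.5_m20
  layout: {n_groups: 2, subjects_per_group: 20, samples_per_subject: 20, replicates_per_sample: 1}
  components: {sigma_subject: 0.7071067811865476, sigma_sample: null, sigma_resid: 0.7071067811865476}
  effect: 0.0
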
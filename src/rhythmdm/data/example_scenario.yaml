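# Example synthetic-cohort scenario: study-sized groups (45/192/153),
# 30 days x 3 prompts, with the example group transition matrices.
n_participants_per_group: {control: 45, bipolar: 192, schizophrenia: 153}
n_days: 30
prompts_per_day: 3
missingness_rate: 0.1
symptom_noise_sd: 2.0
seed: 0
true_transition_matrix_per_group:
  control:
  - [0.042857142857142864, 0.35000000000000003, 0.042857142857142864, 0.042857142857142864, 0.042857142857142864,
    0.042857142857142864, 0.042857142857142864, 0.35000000000000003, 0.042857142857142864]
  - [0.028571428571428574, 0.2, 0.028571428571428574, 0.028571428571428574, 0.028571428571428574, 0.028571428571428574,
    0.028571428571428574, 0.6, 0.028571428571428574]
  - [0.042857142857142864, 0.35000000000000003, 0.042857142857142864, 0.042857142857142864, 0.042857142857142864,
    0.042857142857142864, 0.042857142857142864, 0.35000000000000003, 0.042857142857142864]
  - [0.042857142857142864, 0.35000000000000003, 0.042857142857142864, 0.042857142857142864, 0.042857142857142864,
    0.042857142857142864, 0.042857142857142864, 0.35000000000000003, 0.042857142857142864]
  - [0.042857142857142864, 0.35000000000000003, 0.042857142857142864, 0.042857142857142864, 0.042857142857142864,
    0.042857142857142864, 0.042857142857142864, 0.35000000000000003, 0.042857142857142864]
  - [0.042857142857142864, 0.35000000000000003, 0.042857142857142864, 0.042857142857142864, 0.042857142857142864,
    0.042857142857142864, 0.042857142857142864, 0.35000000000000003, 0.042857142857142864]
  - [0.042857142857142864, 0.35000000000000003, 0.042857142857142864, 0.042857142857142864, 0.042857142857142864,
    0.042857142857142864, 0.042857142857142864, 0.35000000000000003, 0.042857142857142864]
  - [0.028571428571428574, 0.6, 0.028571428571428574, 0.028571428571428574, 0.028571428571428574, 0.028571428571428574,
    0.028571428571428574, 0.2, 0.028571428571428574]
  - [0.042857142857142864, 0.35000000000000003, 0.042857142857142864, 0.042857142857142864, 0.042857142857142864,
    0.042857142857142864, 0.042857142857142864, 0.35000000000000003, 0.042857142857142864]
  bipolar:
  - [0.11142857142857143, 0.203, 0.11142857142857143, 0.04942857142857143, 0.04942857142857143, 0.04942857142857143,
    0.11142857142857143, 0.203, 0.11142857142857143]
  - [0.10428571428571429, 0.128, 0.10428571428571429, 0.04228571428571429, 0.04228571428571429, 0.04228571428571429,
    0.10428571428571429, 0.328, 0.10428571428571429]
  - [0.11142857142857143, 0.203, 0.11142857142857143, 0.04942857142857143, 0.04942857142857143, 0.04942857142857143,
    0.11142857142857143, 0.203, 0.11142857142857143]
  - [0.11142857142857143, 0.203, 0.11142857142857143, 0.04942857142857143, 0.04942857142857143, 0.04942857142857143,
    0.11142857142857143, 0.203, 0.11142857142857143]
  - [0.11142857142857143, 0.203, 0.11142857142857143, 0.04942857142857143, 0.04942857142857143, 0.04942857142857143,
    0.11142857142857143, 0.203, 0.11142857142857143]
  - [0.11142857142857143, 0.203, 0.11142857142857143, 0.04942857142857143, 0.04942857142857143, 0.04942857142857143,
    0.11142857142857143, 0.203, 0.11142857142857143]
  - [0.11142857142857143, 0.203, 0.11142857142857143, 0.04942857142857143, 0.04942857142857143, 0.04942857142857143,
    0.11142857142857143, 0.203, 0.11142857142857143]
  - [0.10428571428571429, 0.328, 0.10428571428571429, 0.04228571428571429, 0.04228571428571429, 0.04228571428571429,
    0.10428571428571429, 0.128, 0.10428571428571429]
  - [0.11142857142857143, 0.203, 0.11142857142857143, 0.04942857142857143, 0.04942857142857143, 0.04942857142857143,
    0.11142857142857143, 0.203, 0.11142857142857143]
  schizophrenia:
  - [0.18, 0.05600000000000001, 0.18, 0.05600000000000001, 0.05600000000000001, 0.05600000000000001, 0.18,
    0.05600000000000001, 0.18]
  - [0.18, 0.05600000000000001, 0.18, 0.05600000000000001, 0.05600000000000001, 0.05600000000000001, 0.18,
    0.05600000000000001, 0.18]
  - [0.18, 0.05600000000000001, 0.18, 0.05600000000000001, 0.05600000000000001, 0.05600000000000001, 0.18,
    0.05600000000000001, 0.18]
  - [0.18, 0.05600000000000001, 0.18, 0.05600000000000001, 0.05600000000000001, 0.05600000000000001, 0.18,
    0.05600000000000001, 0.18]
  - [0.18, 0.05600000000000001, 0.18, 0.05600000000000001, 0.05600000000000001, 0.05600000000000001, 0.18,
    0.05600000000000001, 0.18]
  - [0.18, 0.05600000000000001, 0.18, 0.05600000000000001, 0.05600000000000001, 0.05600000000000001, 0.18,
    0.05600000000000001, 0.18]
  - [0.18, 0.05600000000000001, 0.18, 0.05600000000000001, 0.05600000000000001, 0.05600000000000001, 0.18,
    0.05600000000000001, 0.18]
  - [0.18, 0.05600000000000001, 0.18, 0.05600000000000001, 0.05600000000000001, 0.05600000000000001, 0.18,
    0.05600000000000001, 0.18]
  - [0.18, 0.05600000000000001, 0.18, 0.05600000000000001, 0.05600000000000001, 0.05600000000000001, 0.18,
    0.05600000000000001, 0.18]
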
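{
  "comment": "Published headline results of the national cost-utility analysis: lifetime totals and per-person values by subgroup, in 2022 A$, plus the accompanying results-text counts. Used only for arithmetic consistency checking, never as model inputs.",
  "wtp_threshold": 28033,
  "currency_rate": 0.6947,
  "rows": [
    {
      "name": "base_case", "partition": "base", "n": 61394,
      "cost_nonsurgical": 1092713293, "cost_usual_care": 1582021235, "delta_cost": -489307942,
      "qalys_nonsurgical": 624489, "qalys_usual_care": 650902, "delta_qalys": -26412,
      "inmb_per_person": -4090,
      "per_person": {"cost_nonsurgical": 17798, "cost_usual_care": 25768, "delta_cost": -7970, "qalys_nonsurgical": 10.17, "qalys_usual_care": 10.60, "delta_qalys": -0.43}
    },
    {
      "name": "no_mild", "partition": "baseline_state", "n": 12473,
      "cost_nonsurgical": 215267310, "cost_usual_care": 317132491, "delta_cost": -101865181,
      "qalys_nonsurgical": 128513, "qalys_usual_care": 132142, "delta_qalys": -3629,
      "inmb_per_person": 11,
      "per_person": {"cost_nonsurgical": 17259, "cost_usual_care": 25426, "delta_cost": -8167, "qalys_nonsurgical": 10.30, "qalys_usual_care": 10.59, "delta_qalys": -0.29}
    },
    {
      "name": "moderate", "partition": "baseline_state", "n": 30706,
      "cost_nonsurgical": 546735808, "cost_usual_care": 790850027, "delta_cost": -244114220,
      "qalys_nonsurgical": 316909, "qalys_usual_care": 330169, "delta_qalys": -13260,
      "inmb_per_person": -4156,
      "per_person": {"cost_nonsurgical": 17805, "cost_usual_care": 25755, "delta_cost": -7950, "qalys_nonsurgical": 10.32, "qalys_usual_care": 10.75, "delta_qalys": -0.43}
    },
    {
      "name": "severe_extreme", "partition": "baseline_state", "n": 18215,
      "cost_nonsurgical": 330710175, "cost_usual_care": 474038717, "delta_cost": -143328542,
      "qalys_nonsurgical": 179067, "qalys_usual_care": 188591, "delta_qalys": -9523,
      "inmb_per_person": -6788,
      "per_person": {"cost_nonsurgical": 18156, "cost_usual_care": 26025, "delta_cost": -7869, "qalys_nonsurgical": 9.83, "qalys_usual_care": 10.35, "delta_qalys": -0.52}
    },
    {
      "name": "45-54", "partition": "age_band", "n": 3943,
      "cost_nonsurgical": 91483696, "cost_usual_care": 121227208, "delta_cost": -29743512,
      "qalys_nonsurgical": 51226, "qalys_usual_care": 54724, "delta_qalys": -3498,
      "inmb_per_person": -17326,
      "per_person": {"cost_nonsurgical": 23202, "cost_usual_care": 30745, "delta_cost": -7543, "qalys_nonsurgical": 12.99, "qalys_usual_care": 13.88, "delta_qalys": -0.89}
    },
    {
      "name": "55-64", "partition": "age_band", "n": 16567,
      "cost_nonsurgical": 326072933, "cost_usual_care": 447603176, "delta_cost": -121530243,
      "qalys_nonsurgical": 200279, "qalys_usual_care": 207567, "delta_qalys": -7288,
      "inmb_per_person": -4996,
      "per_person": {"cost_nonsurgical": 19682, "cost_usual_care": 27018, "delta_cost": -7336, "qalys_nonsurgical": 12.09, "qalys_usual_care": 12.53, "delta_qalys": -0.44}
    },
    {
      "name": "65-74", "partition": "age_band", "n": 26240,
      "cost_nonsurgical": 457322473, "cost_usual_care": 660314256, "delta_cost": -202991783,
      "qalys_nonsurgical": 268203, "qalys_usual_care": 278403, "delta_qalys": -10200,
      "inmb_per_person": -3161,
      "per_person": {"cost_nonsurgical": 17428, "cost_usual_care": 25164, "delta_cost": -7736, "qalys_nonsurgical": 10.22, "qalys_usual_care": 10.61, "delta_qalys": -0.39}
    },
    {
      "name": "75-84", "partition": "age_band", "n": 14644,
      "cost_nonsurgical": 217834191, "cost_usual_care": 352876596, "delta_cost": -135042405,
      "qalys_nonsurgical": 104781, "qalys_usual_care": 110208, "delta_qalys": -5427,
      "inmb_per_person": -1166,
      "per_person": {"cost_nonsurgical": 14875, "cost_usual_care": 24097, "delta_cost": -9222, "qalys_nonsurgical": 7.16, "qalys_usual_care": 7.53, "delta_qalys": -0.37}
    },
    {
      "name": "female", "partition": "sex", "n": 33069,
      "cost_nonsurgical": 606179084, "cost_usual_care": 850139140, "delta_cost": -243960056,
      "qalys_nonsurgical": 342503, "qalys_usual_care": 358205, "delta_qalys": -15702,
      "inmb_per_person": -5934,
      "per_person": {"cost_nonsurgical": 18331, "cost_usual_care": 25708, "delta_cost": -7377, "qalys_nonsurgical": 10.36, "qalys_usual_care": 10.83, "delta_qalys": -0.47}
    },
    {
      "name": "male", "partition": "sex", "n": 28325,
      "cost_nonsurgical": 486534209, "cost_usual_care": 731882095, "delta_cost": -245347886,
      "qalys_nonsurgical": 281987, "qalys_usual_care": 292696, "delta_qalys": -10710,
      "inmb_per_person": -1938,
      "per_person": {"cost_nonsurgical": 17177, "cost_usual_care": 25839, "delta_cost": -8662, "qalys_nonsurgical": 9.96, "qalys_usual_care": 10.33, "delta_qalys": -0.38}
    },
    {
      "name": "public", "partition": "hospital", "n": 16514,
      "cost_nonsurgical": 271856461, "cost_usual_care": 390514531, "delta_cost": -118658069,
      "qalys_nonsurgical": 166920, "qalys_usual_care": 174342, "delta_qalys": -7422,
      "inmb_per_person": -5414,
      "per_person": {"cost_nonsurgical": 16462, "cost_usual_care": 23647, "delta_cost": -7185, "qalys_nonsurgical": 10.11, "qalys_usual_care": 10.56, "delta_qalys": -0.45}
    },
    {
      "name": "private", "partition": "hospital", "n": 44878,
      "cost_nonsurgical": 820594644, "cost_usual_care": 1191065311, "delta_cost": -370470667,
      "qalys_nonsurgical": 459045, "qalys_usual_care": 477586, "delta_qalys": -18541,
      "inmb_per_person": -3327,
      "per_person": {"cost_nonsurgical": 18285, "cost_usual_care": 26540, "delta_cost": -8255, "qalys_nonsurgical": 10.23, "qalys_usual_care": 10.64, "delta_qalys": -0.41}
    }
  ],
  "results_text": {
    "fewer_primary_tkr": 11995,
    "fewer_revision_tkr": 2423,
    "fewer_total_tkr": 14418,
    "tkr_avoidance_pct": 19.5,
    "crossover_years": 9,
    "psa_mean_inmb": -4897,
    "psa_ci_low": -5229,
    "psa_ci_high": -4564,
    "psa_pct_lower_cost_lower_qaly": 99.2,
    "psa_pct_cost_effective": 18.6
  },
  "currency_pairs_aud_usd": [
    [24607, 17095],
    [43125, 29959],
    [28033, 19475],
    [1500, 1042],
    [20955, 14557],
    [25435, 17670],
    [43233, 30034],
    [43078, 29926]
  ]
}
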
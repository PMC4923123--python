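# Default non-exercise cardiorespiratory fitness (eCRF) model.
#
# This is a RECONSTRUCTION of the published self-report regression family
# (intercept + gender + age + BMI + resting heart rate + a five-level
# self-reported activity category); the exact published weights are not
# redistributed here.  Coefficients are in METs per unit of each predictor.
# Replace this file with calibrated weights for quantitative eCRF work; all
# downstream profile statistics are invariant to the particular weights
# because fitness enters the analysis only through within-cell rankings.
intercept: 18.07          # MET, baseline
coef_gender: 2.77         # MET, added for the gender level coded 1 (male)
gender_code: {F: 0, M: 1}
coef_age: -0.10           # MET per year
coef_bmi: -0.17           # MET per kg/m^2
coef_hr: -0.03            # MET per beat/min resting heart rate
# Activity category offsets, METs, categories 1..5 (sedentary .. vigorous);
# the span (~3 METs) matches the published self-report model family
coef_activity: [0.00, 0.52, 1.06, 1.76, 3.03]
# PASE weekly minutes -> activity category 1..5.  The table partitions the
# whole (low_exertion_min, aerobic_min) quadrant: aerobic minutes dominate;
# with no aerobic activity the category is set by low-exertion minutes.
activity_thresholds:
  aerobic_high: 180   # aerobic >= 180 min/week          -> category 5
  aerobic_mid: 60     # 60 <= aerobic < 180              -> category 4
                      # 0 < aerobic < 60                 -> category 3
  low_high: 120       # aerobic == 0, low >= 120         -> category 3
  low_mid: 30         # aerobic == 0, 30 <= low < 120    -> category 2
                      # aerobic == 0, low < 30           -> category 1
met_to_vo2max_factor: 3.5   # ml/min/kg per MET
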
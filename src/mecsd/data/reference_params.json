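{
 "Administrative_staff": {
  "bounds": [
   0.02,
   0.6
  ],
  "provenance": "ASSUMED",
  "value": 0.02043
 },
 "Elderly_care_workers": {
  "bounds": [
   0.05,
   0.8
  ],
  "provenance": "ASSUMED",
  "value": 0.09619
 },
 "Facility_and_equipment_investment": {
  "bounds": [
   0.02,
   0.8
  ],
  "provenance": "ASSUMED",
  "value": 0.02005
 },
 "Health_monitoring_equipment": {
  "bounds": [
   0.02,
   0.8
  ],
  "provenance": "ASSUMED",
  "value": 0.02005
 },
 "Information_sharing_system": {
  "bounds": [
   0.02,
   0.8
  ],
  "provenance": "ASSUMED",
  "value": 0.02005
 },
 "Input_conversion_rate": {
  "note": "80% of input becomes service output",
  "provenance": "FIXED",
  "value": 0.8
 },
 "Institutional_employee_satisfaction": {
  "bounds": [
   0.02,
   0.8
  ],
  "provenance": "ASSUMED",
  "value": 0.02005
 },
 "Medical_staff": {
  "bounds": [
   0.05,
   0.8
  ],
  "provenance": "ASSUMED",
  "value": 0.30859
 },
 "Policy_support": {
  "bounds": [
   0.2,
   1.0
  ],
  "provenance": "ASSUMED",
  "value": 0.85765
 },
 "Professionalism_base": {
  "bounds": [
   0.1,
   1.0
  ],
  "provenance": "ASSUMED",
  "value": 0.42293
 },
 "Service_content": {
  "bounds": [
   0.02,
   0.6
  ],
  "provenance": "ASSUMED",
  "value": 0.02004
 },
 "Turnover_rate_of_service_staff": {
  "bounds": [
   0.3,
   1.0
  ],
  "note": "loader floor 0.05 via bounds",
  "provenance": "ASSUMED",
  "value": 0.76599
 },
 "family_satisfaction_delay": {
  "note": "family satisfaction lags the elderly by 2 months",
  "provenance": "FIXED",
  "value": 2.0
 },
 "fin_w_operating": {
  "bounds": [
   0.0,
   0.5
  ],
  "provenance": "ASSUMED",
  "value": 0.0
 },
 "fin_w_subsidy": {
  "bounds": [
   0.05,
   0.6
  ],
  "provenance": "ASSUMED",
  "value": 0.1838
 },
 "initial_increment": {
  "bounds": [
   0.0,
   1.5
  ],
  "note": "profit lag start level",
  "provenance": "ASSUMED",
  "value": 1.49994
 },
 "maturity_gain": {
  "bounds": [
   0.05,
   0.5
  ],
  "provenance": "ASSUMED",
  "value": 0.08752
 },
 "maturity_low": {
  "bounds": [
   0.05,
   0.5
  ],
  "provenance": "ASSUMED",
  "value": 0.36357
 },
 "maturity_scale": {
  "bounds": [
   1.0,
   1.0
  ],
  "note": "scenario lever; always 1 at baseline",
  "provenance": "ASSUMED",
  "value": 1.0
 },
 "operating_investment_base": {
  "note": "initial operating investment",
  "provenance": "FIXED",
  "value": 0.5
 },
 "performance_initial": {
  "note": "stock initial value",
  "provenance": "FIXED",
  "value": 1.0
 },
 "profit_lag": {
  "bounds": [
   1.0,
   1.0
  ],
  "note": "months; fixed",
  "provenance": "ASSUMED",
  "value": 1.0
 },
 "profit_share": {
  "bounds": [
   0.0,
   1.0
  ],
  "note": "share of increment that becomes profit",
  "provenance": "ASSUMED",
  "value": 0.95759
 },
 "profit_step_fraction": {
  "note": "10% of profit reinvested",
  "provenance": "FIXED",
  "value": 0.1
 },
 "profit_step_onset": {
  "note": "profit-financed investment starts in year 3",
  "provenance": "FIXED",
  "value": 36.0
 },
 "recognition_smooth_delay": {
  "bounds": [
   6.0,
   36.0
  ],
  "note": "months",
  "provenance": "ASSUMED",
  "value": 6.0
 },
 "recognition_smooth_init": {
  "bounds": [
   0.0,
   0.5
  ],
  "provenance": "ASSUMED",
  "value": 0.00567
 },
 "smooth_delay_quality": {
  "note": "quality norms take full effect 60 months after release",
  "provenance": "FIXED",
  "value": 60.0
 },
 "smooth_init_quality": {
  "note": "initial smoothed policy level",
  "provenance": "FIXED",
  "value": 0.1
 },
 "subsidy_pulse_end": {
  "provenance": "FIXED",
  "value": 120.0
 },
 "subsidy_pulse_interval": {
  "provenance": "FIXED",
  "value": 12.0
 },
 "subsidy_pulse_start": {
  "provenance": "FIXED",
  "value": 12.0
 },
 "subsidy_pulse_width": {
  "provenance": "FIXED",
  "value": 1.0
 },
 "subsidy_smooth_delay": {
  "bounds": [
   6.0,
   24.0
  ],
  "note": "months",
  "provenance": "ASSUMED",
  "value": 24.0
 },
 "subsidy_smooth_init": {
  "bounds": [
   0.0,
   0.15
  ],
  "provenance": "ASSUMED",
  "value": 3e-05
 },
 "talent_policy_gain": {
  "bounds": [
   0.0,
   1.0
  ],
  "note": "policy-driven talent supply",
  "provenance": "ASSUMED",
  "value": 0.33459
 },
 "talent_smooth_init": {
  "bounds": [
   0.0,
   0.3
  ],
  "provenance": "ASSUMED",
  "value": 5e-05
 },
 "w_elderly": {
  "bounds": [
   0.5,
   0.5
  ],
  "provenance": "ASSUMED",
  "value": 0.5
 },
 "w_employee": {
  "bounds": [
   0.2,
   0.2
  ],
  "provenance": "ASSUMED",
  "value": 0.2
 },
 "w_family": {
  "bounds": [
   0.3,
   0.3
  ],
  "provenance": "ASSUMED",
  "value": 0.3
 },
 "w_input_capital": {
  "provenance": "FIXED",
  "value": 0.2
 },
 "w_input_element": {
  "provenance": "FIXED",
  "value": 0.5
 },
 "w_input_information": {
  "provenance": "FIXED",
  "value": 0.1
 },
 "w_resources_monitoring": {
  "provenance": "FIXED",
  "value": 0.3
 },
 "w_resources_sharing": {
  "provenance": "FIXED",
  "value": 0.3
 },
 "w_satisfaction_personnel": {
  "provenance": "FIXED",
  "value": 0.65
 },
 "w_satisfaction_recognition": {
  "provenance": "FIXED",
  "value": 0.35
 }
}
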
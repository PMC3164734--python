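{
  "schema": "tbm-fixtures/1",
  "description": "Published TBM parameter sets (value, standard error; null error = parameter held fixed). Units: apex_constant and threshold as printed (rate scale / dimensionless), maturation_rate and quiescent_drive in 1/years, middle_age and critical_age in years. critical_age is the reported (freely fitted or extrapolated) value. chi2_origin is the fitting software's reduced form; chi2_conventional the Pearson form used for p-values.",
  "exponent": 9,
  "fixtures": {
    "brazil-2002-males": {
      "country": "Brazil", "year": 2002, "gender": "males", "source": "fit",
      "apex_constant": [60.2, 7.1],
      "threshold": [17.8, 2.4],
      "maturation_rate": [0.189, 0.023],
      "middle_age": [46, null],
      "quiescent_drive": [0.0053, 0.0015],
      "critical_age": [11.7, 0.6],
      "chi2_origin": 0.94, "chi2_conventional": 1.076, "dof": 11, "p_value": ">0.999"
    },
    "brazil-2002-females": {
      "country": "Brazil", "year": 2002, "gender": "females", "source": "fit",
      "apex_constant": [15.9, 6.4],
      "threshold": [11.3, 4.8],
      "maturation_rate": [0.165, 0.070],
      "middle_age": [47, null],
      "quiescent_drive": [-0.001, 0.002],
      "critical_age": [10.7, 2.0],
      "chi2_origin": 0.12, "chi2_conventional": 0.495, "dof": 11, "p_value": ">0.999"
    },
    "sri-lanka-1999-males": {
      "country": "Sri Lanka", "year": 1999, "gender": "males", "source": "fit",
      "apex_constant": [737, 108],
      "threshold": [13.9, 3.3],
      "maturation_rate": [0.093, 0.016],
      "middle_age": [42.2, 0.6],
      "quiescent_drive": [0, null],
      "critical_age": [12.2, 0.8],
      "chi2_origin": 148.3, "chi2_conventional": 25.08, "dof": 10, "p_value": "0.005"
    },
    "usa-2001-males": {
      "country": "USA", "year": 2001, "gender": "males", "source": "fit",
      "apex_constant": [287, 17],
      "threshold": [8.20, 0.76],
      "maturation_rate": [0.0817, 0.0054],
      "middle_age": [46.30, 0.25],
      "quiescent_drive": [0.00416, 0.00089],
      "critical_age": [12.0, 0.4],
      "chi2_origin": 6.76, "chi2_conventional": 21.37, "dof": 68, "p_value": ">0.999"
    },
    "usa-2001-females": {
      "country": "USA", "year": 2001, "gender": "females", "source": "fit",
      "apex_constant": [15.5, 3.7],
      "threshold": [28.6, 6.1],
      "maturation_rate": [0.332, 0.082],
      "middle_age": [47, null],
      "quiescent_drive": [0, null],
      "critical_age": [11.5, 1.1],
      "chi2_origin": 2.11, "chi2_conventional": 32.06, "dof": 71, "p_value": ">0.999"
    },
    "usa-2001-both": {
      "country": "USA", "year": 2001, "gender": "both", "source": "fit",
      "apex_constant": [94.3, 7.9],
      "threshold": [15.2, 1.6],
      "maturation_rate": [0.147, 0.013],
      "middle_age": [47.49, 0.44],
      "quiescent_drive": [0.00195, 0.00078],
      "critical_age": [12.2, 0.5],
      "chi2_origin": 2.10, "chi2_conventional": 10.42, "dof": 68, "p_value": ">0.999"
    },
    "usa-2002-males": {
      "country": "USA", "year": 2002, "gender": "males", "source": "fit",
      "apex_constant": [271, 18],
      "threshold": [9.19, 0.94],
      "maturation_rate": [0.0890, 0.0064],
      "middle_age": [46.56, 0.29],
      "quiescent_drive": [0.00496, 0.00095],
      "critical_age": [12.2, 0.4],
      "chi2_origin": 8.17, "chi2_conventional": 23.60, "dof": 68, "p_value": ">0.999"
    },
    "usa-2002-females": {
      "country": "USA", "year": 2002, "gender": "females", "source": "fit",
      "apex_constant": [18.1, 4.3],
      "threshold": [30.3, 6.9],
      "maturation_rate": [0.292, 0.070],
      "middle_age": [47, null],
      "quiescent_drive": [0, null],
      "critical_age": [12.1, 1.1],
      "chi2_origin": 2.30, "chi2_conventional": 32.69, "dof": 69, "p_value": ">0.999"
    },
    "usa-2002-both": {
      "country": "USA", "year": 2002, "gender": "both", "source": "fit",
      "apex_constant": [91.4, 8.9],
      "threshold": [16.8, 2.0],
      "maturation_rate": [0.155, 0.016],
      "middle_age": [47.69, 0.53],
      "quiescent_drive": [0.00247, 0.00088],
      "critical_age": [12.4, 0.6],
      "chi2_origin": 2.80, "chi2_conventional": 13.47, "dof": 68, "p_value": ">0.999"
    },
    "usa-2003-both": {
      "country": "USA", "year": 2003, "gender": "both", "source": "extrapolation",
      "apex_constant": [88.4, 9.6],
      "threshold": [18.4, 2.4],
      "maturation_rate": [0.163, 0.019],
      "middle_age": [47.9, 0.6],
      "quiescent_drive": [0.003, 0.001],
      "critical_age": [12.6, 0.6],
      "chi2_origin": null, "chi2_conventional": 14.54, "dof": 8, "p_value": "0.069"
    }
  }
}
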
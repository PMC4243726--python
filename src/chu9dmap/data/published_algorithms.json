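{
  "AU/OLS/model1": {
    "form": "index_quadratic", "link": "identity", "estimator_label": "OLS",
    "value_set": "AU_adolescent_BWS",
    "intercept": "-0.435412", "beta1": "0.043515", "beta2": "-0.000334",
    "robust_se": {"const": "0.129225", "ks_index": "0.005291", "ks_index_sq": "0.000053"},
    "truncate_upper_at_1": true
  },
  "AU/CLAD/model1": {
    "form": "index_quadratic", "link": "identity", "estimator_label": "CLAD",
    "value_set": "AU_adolescent_BWS",
    "intercept": "-0.510120", "beta1": "0.046580", "beta2": "-0.000359",
    "robust_se": {"const": "0.160989", "ks_index": "0.006828", "ks_index_sq": "0.000072"},
    "truncate_upper_at_1": true
  },
  "AU/MM/model1": {
    "form": "index_quadratic", "link": "identity", "estimator_label": "MM",
    "value_set": "AU_adolescent_BWS",
    "intercept": "-0.593052", "beta1": "0.049504", "beta2": "-0.000384",
    "robust_se": {"const": "0.157245", "ks_index": "0.006682", "ks_index_sq": "0.000070"},
    "truncate_upper_at_1": true
  },
  "AU/GLM/model1": {
    "form": "index_quadratic", "link": "logit", "estimator_label": "GLM",
    "value_set": "AU_adolescent_BWS",
    "intercept": "-2.472760", "beta1": "0.092650", "beta2": null,
    "robust_se": {"const": "0.359525", "ks_index": "0.008747"},
    "truncate_upper_at_1": true
  },
  "AU/OLS/model2": {
    "form": "item_linear", "link": "identity", "estimator_label": "OLS",
    "value_set": "AU_adolescent_BWS",
    "intercept": "0.250215",
    "gammas": {"ks_i1": "0.035797", "ks_i2": "0.017943", "ks_i3": "0.037163",
               "ks_i4": "0.022713", "ks_i9": "0.016046", "ks_i10": "0.027138"},
    "robust_se": {"const": "0.029866", "ks_i1": "0.008005", "ks_i2": "0.007725",
                  "ks_i3": "0.008005", "ks_i4": "0.006543", "ks_i9": "0.007037",
                  "ks_i10": "0.008991"},
    "truncate_upper_at_1": true
  },
  "AU/CLAD/model2": {
    "form": "item_linear", "link": "identity", "estimator_label": "CLAD",
    "value_set": "AU_adolescent_BWS",
    "intercept": "0.156848",
    "gammas": {"ks_i1": "0.059820", "ks_i3": "0.039315", "ks_i4": "0.027291",
               "ks_i10": "0.060152"},
    "robust_se": {"const": "0.053203", "ks_i1": "0.009940", "ks_i3": "0.011111",
                  "ks_i4": "0.010421", "ks_i10": "0.010321"},
    "truncate_upper_at_1": true
  },
  "AU/MM/model2": {
    "form": "item_linear", "link": "identity", "estimator_label": "MM",
    "value_set": "AU_adolescent_BWS",
    "intercept": "0.222655",
    "gammas": {"ks_i1": "0.037867", "ks_i2": "0.023085", "ks_i3": "0.037192",
               "ks_i4": "0.021284", "ks_i9": "0.024877", "ks_i10": "0.022256"},
    "robust_se": {"const": "0.034914", "ks_i1": "0.010995", "ks_i2": "0.009292",
                  "ks_i3": "0.009329", "ks_i4": "0.007952", "ks_i9": "0.008434",
                  "ks_i10": "0.010361"},
    "truncate_upper_at_1": true
  },
  "AU/GLM/model2": {
    "form": "item_linear", "link": "logit", "estimator_label": "GLM",
    "value_set": "AU_adolescent_BWS",
    "intercept": "-1.735730",
    "gammas": {"ks_i1": "0.296834", "ks_i3": "0.331778", "ks_i10": "0.300356"},
    "robust_se": {"const": "0.167557", "ks_i1": "0.042888", "ks_i3": "0.040524",
                  "ks_i10": "0.041449"},
    "truncate_upper_at_1": true
  },
  "UK/OLS/model1": {
    "form": "index_quadratic", "link": "identity", "estimator_label": "OLS",
    "value_set": "UK_adult_SG",
    "intercept": "-0.075688", "beta1": "0.032434", "beta2": "-0.000249",
    "robust_se": {"const": "0.102939", "ks_index": "0.004171", "ks_index_sq": "0.000041"},
    "truncate_upper_at_1": true
  },
  "UK/CLAD/model1": {
    "form": "index_quadratic", "link": "identity", "estimator_label": "CLAD",
    "value_set": "UK_adult_SG",
    "intercept": "-0.006549", "beta1": "0.029623", "beta2": "-0.000218",
    "robust_se": {"const": "0.097355", "ks_index": "0.004257", "ks_index_sq": "0.000045"},
    "truncate_upper_at_1": true
  },
  "UK/MM/model1": {
    "form": "index_quadratic", "link": "identity", "estimator_label": "MM",
    "value_set": "UK_adult_SG",
    "intercept": "-0.077689", "beta1": "0.032500", "beta2": "-0.000246",
    "robust_se": {"const": "0.102295", "ks_index": "0.004142", "ks_index_sq": "0.000041"},
    "truncate_upper_at_1": true
  },
  "UK/GLM/model1": {
    "form": "index_quadratic", "link": "logit", "estimator_label": "GLM",
    "value_set": "UK_adult_SG",
    "intercept": "-1.749110", "beta1": "0.082786", "beta2": null,
    "robust_se": {"const": "0.316079", "ks_index": "0.007694"},
    "truncate_upper_at_1": true
  },
  "UK/OLS/model2": {
    "form": "item_linear", "link": "identity", "estimator_label": "OLS",
    "value_set": "UK_adult_SG",
    "intercept": "0.437368",
    "gammas": {"ks_i1": "0.026771", "ks_i2": "0.010975", "ks_i3": "0.029050",
               "ks_i4": "0.015820", "ks_i9": "0.013502", "ks_i10": "0.020093"},
    "robust_se": {"const": "0.024759", "ks_i1": "0.006051", "ks_i2": "0.005552",
                  "ks_i3": "0.006725", "ks_i4": "0.005122", "ks_i9": "0.005639",
                  "ks_i10": "0.007056"},
    "truncate_upper_at_1": true
  },
  "UK/CLAD/model2": {
    "form": "item_linear", "link": "identity", "estimator_label": "CLAD",
    "value_set": "UK_adult_SG",
    "intercept": "0.440167",
    "gammas": {"ks_i1": "0.025167", "ks_i2": "0.022333", "ks_i3": "0.028383",
               "ks_i4": "0.015550", "ks_i9": "0.025567"},
    "robust_se": {"const": "0.032133", "ks_i1": "0.008471", "ks_i2": "0.006579",
                  "ks_i3": "0.007295", "ks_i4": "0.006502", "ks_i9": "0.004682"},
    "truncate_upper_at_1": true
  },
  "UK/MM/model2": {
    "form": "item_linear", "link": "identity", "estimator_label": "MM",
    "value_set": "UK_adult_SG",
    "intercept": "0.451961",
    "gammas": {"ks_i1": "0.022931", "ks_i2": "0.018505", "ks_i3": "0.022030",
               "ks_i4": "0.014684", "ks_i9": "0.023993", "ks_i10": "0.012365"},
    "robust_se": {"const": "0.024881", "ks_i1": "0.007461", "ks_i2": "0.006152",
                  "ks_i3": "0.006130", "ks_i4": "0.005477", "ks_i9": "0.004852",
                  "ks_i10": "0.006212"},
    "provenance_note": "ks_i10 coefficient 0.012365: ambiguous column assignment in the flattened source table (CLAD vs MM); assigned to MM pending verification against the typeset table.",
    "truncate_upper_at_1": true
  },
  "UK/GLM/model2": {
    "form": "item_linear", "link": "logit", "estimator_label": "GLM",
    "value_set": "UK_adult_SG",
    "intercept": "-1.080010",
    "gammas": {"ks_i1": "0.257334", "ks_i3": "0.298660", "ks_i10": "0.271802"},
    "robust_se": {"const": "0.162497", "ks_i1": "0.038624", "ks_i3": "0.038848",
                  "ks_i10": "0.037553"},
    "truncate_upper_at_1": true
  }
}
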
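term,level,cfpm_hr,cfpm_lo,cfpm_hi,cpm_hr,cpm_lo,cpm_hi,fpm_hr,fpm_lo,fpm_hi,cm_hr,cm_lo,cm_hi,fm_hr,fm_lo,fm_hi,cfm_hr,cfm_lo,cfm_hi
sex,Female,0.92,0.85,0.99,0.95,0.89,1.01,0.92,0.86,0.99,0.95,0.9,1.0,0.89,0.81,0.97,0.91,0.84,0.98
age_group,29-35,0.79,0.69,0.9,0.81,0.7,0.93,0.8,0.7,0.92,0.82,0.73,0.93,0.76,0.64,0.89,0.76,0.66,0.87
age_group,36-45,0.55,0.49,0.62,0.62,0.55,0.7,0.56,0.5,0.64,0.66,0.59,0.73,0.51,0.44,0.59,0.53,0.46,0.6
age_group,>45,0.31,0.28,0.35,0.41,0.37,0.47,0.32,0.28,0.36,0.45,0.41,0.5,0.26,0.22,0.3,0.29,0.26,0.33
health_region,Lleida,1.09,0.91,1.3,1.14,0.99,1.31,1.12,0.94,1.34,1.12,1.0,1.26,1.08,0.87,1.33,1.09,0.9,1.3
health_region,Camp de Tarragona,1.19,1.03,1.37,1.13,0.99,1.28,1.22,1.06,1.41,1.13,1.01,1.26,1.35,1.13,1.61,1.22,1.05,1.41
health_region,Terres de l'Ebre,1.19,0.96,1.47,1.26,1.08,1.48,1.17,0.94,1.46,1.22,1.06,1.39,1.14,0.88,1.48,1.17,0.93,1.46
health_region,Girona,0.88,0.79,0.97,0.92,0.84,1.0,0.88,0.79,0.98,0.92,0.85,0.99,0.86,0.76,0.97,0.86,0.77,0.96
health_region,Catalunya Central,0.94,0.82,1.08,0.95,0.85,1.06,0.95,0.83,1.09,0.96,0.87,1.06,0.95,0.81,1.12,0.95,0.82,1.09
health_region,Alt Pirineu i Aran,0.86,0.56,1.31,0.96,0.72,1.27,0.84,0.54,1.29,0.96,0.75,1.24,0.79,0.47,1.31,0.84,0.54,1.3
activity_branch,"Manufacturing industry, energy production",0.67,0.34,1.3,0.7,0.38,1.27,0.68,0.35,1.35,0.73,0.44,1.21,0.7,0.32,1.51,0.68,0.34,1.35
activity_branch,Construction,0.55,0.28,1.08,0.62,0.34,1.14,0.57,0.29,1.13,0.66,0.4,1.09,0.55,0.25,1.2,0.55,0.28,1.11
activity_branch,Commercial/vehicles repair,0.59,0.3,1.15,0.64,0.35,1.17,0.61,0.31,1.21,0.68,0.41,1.12,0.58,0.27,1.26,0.59,0.3,1.18
activity_branch,"Hotel, restaurant businesses",0.53,0.27,1.05,0.57,0.31,1.06,0.54,0.27,1.08,0.61,0.36,1.02,0.52,0.23,1.14,0.53,0.26,1.07
activity_branch,Transportation/communication,0.68,0.34,1.33,0.7,0.38,1.3,0.7,0.35,1.4,0.74,0.44,1.24,0.69,0.31,1.51,0.68,0.34,1.37
activity_branch,"Finance, real estate, services",0.59,0.3,1.15,0.64,0.35,1.18,0.6,0.3,1.19,0.68,0.41,1.12,0.57,0.26,1.25,0.59,0.3,1.18
activity_branch,Government,0.59,0.3,1.15,0.63,0.34,1.15,0.6,0.3,1.19,0.67,0.4,1.11,0.59,0.27,1.29,0.59,0.3,1.18
activity_branch,"Health, education, other social activities",0.61,0.31,1.19,0.65,0.36,1.2,0.62,0.31,1.23,0.69,0.42,1.15,0.62,0.29,1.35,0.61,0.31,1.22
activity_branch,Domestic housekeeping,0.49,0.2,1.23,0.6,0.3,1.21,0.5,0.19,1.27,0.65,0.36,1.19,0.44,0.15,1.35,0.49,0.19,1.27
activity_branch,Extraterritorial agencies,0.28,0.1,0.77,0.41,0.2,0.8,0.28,0.1,0.79,0.45,0.25,0.81,0.23,0.07,0.77,0.28,0.1,0.79
regime,Self-employed,0.73,0.65,0.82,0.84,0.78,0.91,0.7,0.62,0.79,0.86,0.8,0.92,0.6,0.52,0.69,0.71,0.62,0.8
entity,Insurance company,1.05,0.98,1.12,1.03,0.97,1.09,1.05,0.98,1.13,1.02,0.97,1.08,1.06,0.98,1.15,1.05,0.97,1.12
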
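# Species parameter fixture: 14 volatile halogenated hydrocarbons (6 Montreal-Protocol
# regulated CFCs/ODSs, 8 unregulated chlorinated VSLSs) from a summer urban campaign.
# Columns:
#   name, category      - identifier and regulatory class (regulated_CFC | unregulated_VSLS)
#   mw                  - molecular weight, g/mol
#   lifetime            - atmospheric lifetime, years
#   odp, gwp100         - ozone depletion potential / 100-yr global warming potential
#                         (empty where not defined for the compound)
#   mdl                 - method detection limit, pptv (representative values within the
#                         analytical method's reported 2-17 pptv range)
#   background          - concurrent Northern-Hemisphere background mixing ratio, pptv
#                         (NOAA-GML Mauna Loa / AGAGE Jungfraujoch & Monte Cimone; empty
#                         where no background record exists)
#   iur                 - inhalation unit risk, per ug/m3. Sources: IRIS (1,2-dichloroethane
#                         2.6e-5; chloroform 2.3e-5; carbon tetrachloride 6.0e-6;
#                         trichloroethylene 4.1e-6; tetrachloroethylene 2.6e-7;
#                         methylene chloride 1.0e-8); OEHHA (1,2-dichloropropane 3.7e-6;
#                         1,1-dichloroethane 1.6e-6). Empty = no published IUR.
#   rfc                 - inhalation reference concentration, mg/m3. Sources: IRIS
#                         (trichloroethylene 0.002; 1,2-dichloropropane 0.004;
#                         chloromethane 0.09; bromomethane 0.005; carbon tetrachloride 0.1;
#                         tetrachloroethylene 0.04; methylene chloride 0.6); OEHHA chronic
#                         REL (chloroform 0.3; 1,2-dichloroethane 0.4); provisional
#                         HEAST-style value (1,1-dichloroethane 0.5). Empty = none.
#   campaign_mean, campaign_sd - campaign mean and SD mixing ratio, pptv
name,category,mw,lifetime,odp,gwp100,mdl,background,iur,rfc,campaign_mean,campaign_sd
Freon-12,regulated_CFC,120.91,102,0.75,12500,4,501,,,563,20
Freon-114,regulated_CFC,170.92,189,0.53,9450,2,16,,,17,4
Bromomethane,regulated_CFC,94.94,0.80,0.57,2,2,6.6,,0.005,21,1
Freon-11,regulated_CFC,137.37,52,1,6410,3,227,,,264,15
Freon-113,regulated_CFC,187.38,93,0.82,6530,2,71,,,81,3
Carbon tetrachloride,regulated_CFC,153.82,32,0.87,2150,3,78,6.0e-6,0.1,92,9
Chloromethane,unregulated_VSLS,50.49,0.90,0.02,6,8,493,,0.09,785,261
Methylene chloride,unregulated_VSLS,84.93,0.49,,11,10,49,1.0e-8,0.6,563,505
"1,1-Dichloroethane",unregulated_VSLS,98.96,0.37,,4,6,,1.6e-6,0.5,73,47
Chloroform,unregulated_VSLS,119.38,0.50,,20,5,9.8,2.3e-5,0.3,64,39
"1,2-Dichloroethane",unregulated_VSLS,98.96,0.23,,1,9,,2.6e-5,0.4,265,279
"1,2-Dichloropropane",unregulated_VSLS,112.99,0.07,,,6,,3.7e-6,0.004,67,37
Trichloroethylene,unregulated_VSLS,131.39,0.02,,,4,1.7,4.1e-6,0.002,42,10
Tetrachloroethylene,unregulated_VSLS,165.83,0.30,,6,3,3.3,2.6e-7,0.04,27,15
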
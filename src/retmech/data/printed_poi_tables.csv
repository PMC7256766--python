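label,metric,variant,poi1,poi2,poi3,poi4
settling,von_mises,static,184.55,421.95,610.89,791.25
settling,displacement_um,static,2.41,3.72,5.47,2.71
settling,vol_strain,static,-0.002672,-0.00272,-0.00293,-0.00281
rh,von_mises,static,265.84,598.37,823.69,1082.19
rh,displacement_um,static,3.37,5.66,8.15,4.13
rh,vol_strain,static,-0.0037,-0.0038,-0.0041,-0.0040
baseline,von_mises,static,418.72,908.06,1165.47,1560.17
baseline,displacement_um,static,5.53,8.51,13.2,6.55
baseline,vol_strain,static,-0.0057,-0.0059,-0.0063,-0.0062
tbi,von_mises,static,511.58,1160.99,1300.33,1843.46
tbi,displacement_um,static,7.26,11.2,17.9,9.01
tbi,vol_strain,static,-0.0073,-0.0074,-0.0081,-0.0079
shaking,von_mises,max,480.75,1088.55,1242.30,1784.94
shaking,von_mises,average,420.87,919.21,1144.93,1561.08
shaking,displacement_um,max,6.04,10.19,17.69,8.92
shaking,displacement_um,average,5.56,8.64,13.46,6.74
shaking,vol_strain,max,-0.0067,-0.0069,-0.0076,-0.0075
shaking,vol_strain,average,-0.0058,-0.0059,-0.0064,-0.0062
aht,von_mises,max,578.44,1361.53,1321.47,1969.40
aht,von_mises,average,514.30,1154.18,1285.54,1816.51
aht,displacement_um,max,8.04,13.33,23.82,12.25
aht,displacement_um,average,7.33,11.21,17.80,9.01
aht,vol_strain,max,-0.0082,-0.0086,-0.0096,-0.0095
aht,vol_strain,average,-0.0074,-0.0073,-0.0080,-0.0078
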